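# Element symbol <TAB> element name, used by the formula grammar of the
# synthetic-corpus generator and as lexicon distractor material.
H	hydrogen
He	helium
Li	lithium
Be	beryllium
B	boron
C	carbon
N	nitrogen
O	oxygen
F	fluorine
Ne	neon
Na	sodium
Mg	magnesium
Al	aluminium
Si	silicon
P	phosphorus
S	sulfur
Cl	chlorine
Ar	argon
K	potassium
Ca	calcium
Ti	titanium
Cr	chromium
Mn	manganese
Fe	iron
Co	cobalt
Ni	nickel
Cu	copper
Zn	zinc
As	arsenic
Se	selenium
Br	bromine
Sr	strontium
Mo	molybdenum
Ag	silver
Cd	cadmium
Sn	tin
I	iodine
Ba	barium
W	tungsten
Pt	platinum
Au	gold
Hg	mercury
Pb	lead
Bi	bismuth
U	uranium
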