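# Relative ionic mobilities (K+ = 1) for Henderson junction-potential
# calculation, derived from limiting molar conductivities at 25 C via
# u_rel = lambda_molar / (z^2 * lambda_molar(K+)), lambda_molar(K+) = 73.5
# S cm^2 mol^-1.  Small-ion values from standard conductivity tables
# (Robinson & Stokes; CRC Handbook); organic buffer/chelator values follow
# the tabulations distributed with patch-clamp junction-potential software
# (Barry/JPCalc lineage).  Entries marked "est." are order-of-magnitude
# estimates from structurally similar ions; they enter only at low mM.
# name	charge	mobility	note
K	1	1.000	reference
Na	1	0.682	50.1/73.5
Li	1	0.525	38.6/73.5
Cs	1	1.050	77.2/73.5
NH4	1	1.003	73.7/73.5
H	1	4.757	349.7/73.5
TEA	1	0.444	tetraethylammonium 32.7/73.5
TMA	1	0.611	tetramethylammonium 44.9/73.5
4AP	1	0.450	4-aminopyridinium, est. pyridinium-like
Ca	2	0.405	119/(4*73.5)
Mg	2	0.361	106/(4*73.5)
Ba	2	0.433	127.3/(4*73.5)
Cl	-1	1.039	76.35/73.5
Br	-1	1.063	78.1/73.5
NO3	-1	0.972	71.44/73.5
HCO3	-1	0.605	44.5/73.5
H2PO4	-1	0.449	33/73.5
SO4	-2	0.544	160/(4*73.5)
acetate	-1	0.556	40.9/73.5
gluconate	-1	0.330	JPCalc lineage
methanesulfonate	-1	0.660	~48.5/73.5
methylsulfate	-1	0.663	48.7/73.5
HEPES	-1	0.300	~22/73.5, JPCalc lineage
MOPS	-1	0.300	est. HEPES-like
EGTA	-2	0.240	JPCalc lineage
kynurenate	-1	0.440	est. benzoate-like aromatic carboxylate
OH	-1	2.690	197.7/73.5
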