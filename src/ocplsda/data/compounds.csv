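name,formula,class,fragments
Muconic dialdehyde,C6H6O2,Fatty aldehyde,
3-Methoxybenzenepropanoic acid,C10H12O3,Unsaturated hydroxy fatty acid,
4-Hydroxynonenal alkyne,C9H12O2,Oxylipin,
Leucinic acid,C6H12O3,Hydroxy acid,85.0653
4-Hydroxy-3-methylbenzoic acid,C8H8O3,Hydroxy fatty acid,136.0168
2-Hydroxycaprylic acid,C8H16O3,Hydroxy fatty acid,135.0446
3-Oxo-dodecanoic acid,C12H22O3,Oxo fatty acid,
S-Adenosylmethionine,C15H22N6O5S,Nucleoside,
"3b,16a-Dihydroxyandrostenone sulfate (DHEAS)",C19H28O6S,Sulphated steroid,96.9582
Phosphatidylcholine (synthetic exemplar),C42H82NO7P,Glycerophosphocholine,
Hydropyridine,,Hydropyridine,
Dicarboxylic unsaturated fatty acid,,Dicarboxylic unsaturated fatty acid,"153.0921;135.0815;111.0451"
Amino acid chain,,Amino acid chain,
Sulphated steroid,,Sulphated steroid,96.9582
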