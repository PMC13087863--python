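code3,code1,name,charge_pH7,positions,hydrophobic,light_hydrophobe,sidechain_smiles
NCys,C,N-(2-mercaptoethyl)glycine,0,xy,0,0,CCS
NAsp,D,N-(2-carboxyethyl)glycine,-1,xy,0,0,CCC(=O)[O-]
NGlu,E,N-(3-carboxypropyl)glycine,-1,xy,0,0,CCCC(=O)[O-]
NPhe,F,N-benzylglycine,0,y,1,1,Cc{A}ccccc{A}
Gly,G,glycine,0,,0,0,
NHis,H,N-(4-imidazolyl)ethylglycine,0,y,0,0,CCc{A}[nH]cnc{A}
NIle,I,N-sec-butylglycine,0,y,1,1,C(C)CC
NLys,K,N-(4-aminobutyl)glycine,1,xy,0,0,CCCC[NH3+]
NLeu,L,N-isobutylglycine,0,y,1,1,CC(C)C
NMet,M,N-(2-methylthioethyl)glycine,0,y,0,0,CCSC
NAsn,N,N-(2-carbamoylethyl)glycine,0,y,0,0,CCC(N)=O
Pro,P,proline (pyrrolidine ring),0,,0,0,pyrrolidine
NGln,Q,N-(3-carbamoylpropyl)glycine,0,y,0,0,CCCC(N)=O
NThr,T,N-(1-hydroxyethyl)glycine,0,y,0,0,C(C)O
NVal,V,N-isopropylglycine,0,y,1,0,C(C)C
NTrp,W,N-(indol-3-ylmethyl)glycine,0,y,1,0,Cc{A}c[nH]c{B}ccccc{A}{B}
Nae,X,N-(2-aminoethyl)glycine,1,xy,0,0,CC[NH3+]
NTyr,Y,N-(p-hydroxybenzyl)glycine,0,y,1,1,Cc{A}ccc(O)cc{A}
Nspe,Z,N-(S-1-phenylethyl)glycine,0,y,1,0,[C@@H](C)c{A}ccccc{A}
Ntbu,1,N-tert-butylglycine,0,y,1,0,C(C)(C)C
Nbrpm,3,N-(4-bromomethylbenzyl)glycine,0,y,1,0,Cc{A}ccc(CBr)cc{A}
Nbrpe,4,N-(4-bromoethylbenzyl)glycine,0,y,1,0,Cc{A}ccc(CCBr)cc{A}
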