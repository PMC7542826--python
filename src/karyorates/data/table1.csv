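order,genus,n_samples,mean_xo,mean_xy,mean_multixy,label_xo_xy,label_to_multixy
Blattodea,Cryptotermes,6,23,16.4,,fusion,
Dermaptera,Forficula,14,11,10.8,,fusion,
Dermaptera,Nala,3,17.5,17,,fusion,
Dermaptera,Nesogaster,2,10,9,,fusion,
Mantodea,Deiphobe,2,9,,12,,fission
Orthoptera,Aleuas,6,9,9.2,,neither,
Orthoptera,Dichroplus,35,10.74,8.7,19,fusion,fission
Orthoptera,Diponthus,7,10.5,10,,fusion,
Orthoptera,Eurotettix,5,10,9,,fusion,
Orthoptera,Gryllotalpa,5,9.67,,5,,fusion
Orthoptera,Isophya,25,15,14,,fusion,
Orthoptera,Leiotettix,10,11,8,5.5,fusion,fusion
Orthoptera,Scotussa,8,10.6,8.5,9,fusion,fission
Orthoptera,Scyllina,3,11,10,,fusion,
Orthoptera,Tetrixocephalus,5,11,10,,fusion,
Orthoptera,Xyleus,9,11,10,,fusion,
Orthoptera,Zoniopoda,6,11,10,,fusion,
Phasmatodea,Didymuria,11,17.6,,14.67,,fusion
Phasmatodea,Isagoras,3,18,16,,fusion,
Phasmatodea,Leptynia,5,18.25,,17,,fusion
Phasmatodea,Podacanthus,3,17,,13,,fusion
Phasmatodea,Prisopus,2,24,,13,,fusion
Plecoptera,Perla,7,9.5,4,11.75,fusion,fission
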