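rank,feature,wals_id,rho,sigma,tau
1,Hand and finger(s) identical,130A,0.12142,0.18876,1.21789
2,Lateral consonants,8A,0.83245,0.22907,0.63618
3,Question particle,92A,0.59955,0.39077,0.56961
4,Front rounded vowels,11A,0.06584,0.09890,0.53281
5,Indefinite marker,38A,0.44569,0.38193,0.37116
6,Definite marker,37A,0.60806,0.36313,0.33385
7,Adpositions,48A,0.83333,0.20930,0.31049
8,Verbal person marking,100A,0.77895,0.25744,0.29686
9,Grammatical evidentials,77A,0.56699,0.36507,0.27513
10,Voicing contrast,4A,0.68078,0.32122,0.26579
11,Postverbal negative morpheme,143F,0.46224,0.34988,0.18558
12,Preverbal negative morpheme,143E,0.70544,0.29141,0.18094
13,Zero copula for predicate nominals,120A,0.45337,0.32420,0.11337
14,Passive construction,107A,0.43432,0.31892,0.10915
15,Gender in independent personal pronouns,44A,0.32804,0.28686,0.10814
16,Plural,33A,0.90901,0.10821,0.10752
17,Glottalized consonants,7A,0.27866,0.25397,0.08912
18,Uvular consonants,6A,0.17108,0.17617,0.07762
19,Tense-aspect inflection,69A,0.86561,0.14372,0.07507
20,Inflectional optative,73A,0.15047,0.15337,0.06375
21,Inflectional morphology,26A,0.85552,0.14203,0.04492
22,Morphological second-person imperative,70A,0.77697,0.19176,0.03745
23,Shared encoding of nominal and locational predication,119A,0.30311,0.23385,0.03724
24,Possessive affixes,57A,0.71175,0.22579,0.03463
25,Hand and arm identical,129A,0.36791,0.25061,0.03016
26,Tone,13A,0.41746,0.21060,0.00626
27,Order of degree word and adjective is DegAdj,91A,0.54177,0.21376,0.00595
28,Order of adjective and noun is AdjN,87A,0.29736,0.17745,0.00533
29,Productive reduplication,27A,0.85054,0.10143,0.00361
30,Order of subject and verb is SV,82A,0.86013,0.08752,0.00145
31,Velar nasal,9A,0.49893,0.18057,0.00139
32,Order of numeral and noun is NumN,89A,0.44015,0.16075,0.00053
33,Order of object and verb is OV,83A,0.50317,0.15203,0.00027
34,Order of genitive and noun is GenN,86A,0.59497,0.13545,0.00011
35,Ordinal numerals,53A,0.89720,0.04624,0.00005
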