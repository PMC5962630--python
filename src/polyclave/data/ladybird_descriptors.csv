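id,name,category,n_states,xper_index_full_base,in_minimal_set
1,Pronotum colours,pronotum,7,0.09,False
2,Pattern on pronotum,pronotum,2,0.11,False
3,Number of pronotum patterns,pronotum,9,0.71,True
4,Type of pronotum patterns,pronotum,10,0.85,True
5,Elytra main colour (background),elytra,7,0.53,True
6,Elytra markings,elytra,2,0.12,True
7,Colour of elytra markings,elytra,6,0.52,False
8,Number of elytra markings,elytra,12,0.85,True
9,Type of elytra markings,elytra,6,0.32,True
10,Number of lateral lines in the elytra markings,elytra,8,0.83,False
11,Number of longitudinal lines in the elytra markings,elytra,7,0.82,True
12,A spot in the first third of the elytra,elytra,2,0.4,True
13,One of the spots reaches the rim of the elytra,elytra,2,0.49,True
14,Cream ring around dots,elytra,2,0.06,False
15,Dark sutural elytra band,elytra,2,0.18,True
16,Scutellar spot,elytra,2,0.46,False
17,Shape of the scutellar spot,elytra,4,0.68,False
18,White marks between the scutellar spot and the elytra basis,elytra,2,0.47,False
19,Distinct rim around the edge of the elytra,elytra,2,0.14,False
20,Elytra covered with short hairs,elytra,2,0.12,False
21,Small white triangular marks on the underside below both the middle and front legs,underside,2,0.03,True
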