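,coccinella_venusta,coccinella_hieroglyphica,coccinella_magnifica,coccinella_quinquepunctata,coccinella_septempunctata,coccinella_undecimpunctata
1. Pronotum colours,Black; White,Black; White,Black; White,Black; White,Black; White,Black; White
2. Elytra main colour (background),Black; Orange,Black; Orange,Red; Orange,Red; Orange,Red; Orange,Red; Orange
3. Pattern on pronotum,Present,Present,Present,Present,Present,Present
4. Number of pronotum patterns,2,2,2,2,2,2
5. Type of pronotum patterns,"Central structure (solid, trapezium) with 2 anterior-lateral white or orange marks","Central structure (solid, trapezium) with 2 anterior-lateral white or orange marks","Central structure (solid, trapezium) with 2 anterior-lateral white or orange marks","Central structure (solid, trapezium) with 2 anterior-lateral white or orange marks","Central structure (solid, trapezium) with 2 anterior-lateral white or orange marks","Central structure (solid, trapezium) with 2 anterior-lateral white or orange marks"
6. Elytra markings,Present,Present,Present,Present,Present,Present
7. Colour of elytra markings,Red; Orange; Black,Black,Black,Black,Black,Black
8. Number of elytra markings,1; 2,7,7,5,7,10–14
9. Type of elytra markings,Other,Ovoid shape spot; Other,Regular dots,Regular dots,Regular dots,Regular dots
10. Number of lateral lines of elytra markings,not applicable,3,3,3,3,3
11. Number of longitudinal lines of elytra markings,not applicable,4,5,5,5,5
12. Scutellar spot,Absent,Absent,Present,Present,Present,Present
13. Distinct rim around the edge of the elytra,absent,absent,absent,absent,absent,absent
14. Elytra covered in short hairs,No,No,No,No,No,No
15. Small white triangular marks on the underside below both the middle and front legs,Absent,Absent,Present,Absent,Absent,Absent
16. Cream ring around dots,Absent,Absent,Absent,Absent,Absent,Absent
17. Dark sutural elytra band,Absent,Absent,Absent,Absent,Absent,Absent
18. Shape of the scutellar spot,not applicable,not applicable,A drop (spot with a neck),A drop (spot with a neck),A drop (spot with a neck),A drop (spot with a neck)
19. White marks between the scutellar spot and the basis of elytra,not applicable,not applicable,Present,Present,Present,Present
20. One of the spots reaches the rim of the elytra,No,Yes,No,No,No,No
21. A spot in the first third of the elytra,Absent,Present,Present,Absent,Present,Present
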