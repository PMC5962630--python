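{
 "name": "coccinella_table4",
 "comment": "Descriptive model for the six-species Coccinella comparison matrix. The matrix CSV keeps the printed row order and labels; row_map sends each matrix row to the canonical descriptor numbering (1-21) used throughout the package. States never shown in the matrix (the complement of a constant presence/absence character, a second count for a constant numeric character) are added so every descriptor keeps at least two states; for binary characters the resulting vocabulary size matches the published per-descriptor state counts.",
 "row_map": {"1": 1, "2": 5, "3": 2, "4": 3, "5": 4, "6": 6, "7": 7, "8": 8,
             "9": 9, "10": 10, "11": 11, "12": 16, "13": 19, "14": 20,
             "15": 21, "16": 14, "17": 15, "18": 17, "19": 18, "20": 13,
             "21": 12},
 "descriptors": [
  {"id": 1, "name": "Pronotum colours", "category": "pronotum",
   "states": ["Black", "White"], "depends_on": null},
  {"id": 2, "name": "Pattern on pronotum", "category": "pronotum",
   "states": ["Present", "Absent"], "depends_on": null},
  {"id": 3, "name": "Number of pronotum patterns", "category": "pronotum",
   "states": ["1", "2"], "depends_on": {"parent": 2, "states": ["Present"]}},
  {"id": 4, "name": "Type of pronotum patterns", "category": "pronotum",
   "states": ["Central structure (solid, trapezium) with 2 anterior-lateral white or orange marks", "Other"],
   "depends_on": {"parent": 2, "states": ["Present"]}},
  {"id": 5, "name": "Elytra main colour (background)", "category": "elytra",
   "states": ["Black", "Red", "Orange"], "depends_on": null},
  {"id": 6, "name": "Elytra markings", "category": "elytra",
   "states": ["Present", "Absent"], "depends_on": null},
  {"id": 7, "name": "Colour of elytra markings", "category": "elytra",
   "states": ["Red", "Orange", "Black"],
   "depends_on": {"parent": 6, "states": ["Present"]}},
  {"id": 8, "name": "Number of elytra markings", "category": "elytra",
   "states": ["1", "2", "5", "7", "10–14"],
   "depends_on": {"parent": 6, "states": ["Present"]}},
  {"id": 9, "name": "Type of elytra markings", "category": "elytra",
   "states": ["Regular dots", "Ovoid shape spot", "Other"],
   "depends_on": {"parent": 6, "states": ["Present"]}},
  {"id": 10, "name": "Number of lateral lines in the elytra markings",
   "category": "elytra", "states": ["0", "3"],
   "depends_on": {"parent": 9, "states": ["Regular dots", "Ovoid shape spot"]}},
  {"id": 11, "name": "Number of longitudinal lines in the elytra markings",
   "category": "elytra", "states": ["4", "5"],
   "depends_on": {"parent": 9, "states": ["Regular dots", "Ovoid shape spot"]}},
  {"id": 12, "name": "A spot in the first third of the elytra",
   "category": "elytra", "states": ["Absent", "Present"],
   "depends_on": {"parent": 6, "states": ["Present"]}},
  {"id": 13, "name": "One of the spots reaches the rim of the elytra",
   "category": "elytra", "states": ["Yes", "No"],
   "depends_on": {"parent": 6, "states": ["Present"]}},
  {"id": 14, "name": "Cream ring around dots", "category": "elytra",
   "states": ["Absent", "Present"],
   "depends_on": {"parent": 6, "states": ["Present"]}},
  {"id": 15, "name": "Dark sutural elytra band", "category": "elytra",
   "states": ["Absent", "Present"],
   "depends_on": {"parent": 6, "states": ["Present"]}},
  {"id": 16, "name": "Scutellar spot", "category": "elytra",
   "states": ["Absent", "Present"],
   "depends_on": {"parent": 6, "states": ["Present"]}},
  {"id": 17, "name": "Shape of the scutellar spot", "category": "elytra",
   "states": ["A drop (spot with a neck)", "Other"],
   "depends_on": {"parent": 16, "states": ["Present"]}},
  {"id": 18, "name": "White marks between the scutellar spot and the elytra basis",
   "category": "elytra", "states": ["Present", "Absent"],
   "depends_on": {"parent": 16, "states": ["Present"]}},
  {"id": 19, "name": "Distinct rim around the edge of the elytra",
   "category": "elytra", "states": ["absent", "present"],
   "depends_on": {"parent": 6, "states": ["Present"]}},
  {"id": 20, "name": "Elytra covered with short hairs", "category": "elytra",
   "states": ["No", "Yes"], "depends_on": null},
  {"id": 21, "name": "Small white triangular marks on the underside below both the middle and front legs",
   "category": "underside", "states": ["Absent", "Present"], "depends_on": null}
 ],
 "taxa": [
  {"id": "coccinella_venusta", "name": "Coccinella venusta", "form": null,
   "genus": "Coccinella", "tribe": "Coccinellini", "is_form": false},
  {"id": "coccinella_hieroglyphica", "name": "Coccinella hieroglyphica",
   "form": null, "genus": "Coccinella", "tribe": "Coccinellini", "is_form": false},
  {"id": "coccinella_magnifica", "name": "Coccinella magnifica", "form": null,
   "genus": "Coccinella", "tribe": "Coccinellini", "is_form": false},
  {"id": "coccinella_quinquepunctata", "name": "Coccinella quinquepunctata",
   "form": null, "genus": "Coccinella", "tribe": "Coccinellini", "is_form": false},
  {"id": "coccinella_septempunctata", "name": "Coccinella septempunctata",
   "form": null, "genus": "Coccinella", "tribe": "Coccinellini", "is_form": false},
  {"id": "coccinella_undecimpunctata", "name": "Coccinella undecimpunctata",
   "form": null, "genus": "Coccinella", "tribe": "Coccinellini", "is_form": false}
 ]
}
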