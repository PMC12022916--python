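author_class_loyalty: 0.4
author_core_loyalty: 0.9
author_decoration_loyalty: 0.8
author_partner_loyalty: 0.75
author_pref_decorations: 6
authors_pool_size: 240
class_table:
- class_code: 1.6.1
  intro_year: null
  transform_id: amine_alkylation
  weight_end: 0.8
  weight_start: 1.0
- class_code: 1.7.1
  intro_year: null
  transform_id: williamson_ether
  weight_end: 0.75
  weight_start: 0.95
- class_code: 2.1.1
  intro_year: null
  transform_id: amide_coupling
  weight_end: 1.5
  weight_start: 1.2
- class_code: 2.1.2
  intro_year: null
  transform_id: fischer_esterification
  weight_end: 1.3
  weight_start: 1.2
- class_code: 3.1.1
  intro_year: null
  transform_id: suzuki_bromo
  weight_end: 1.5
  weight_start: 0.3
- class_code: 3.1.2
  intro_year: 2003
  transform_id: suzuki_chloro
  weight_end: 1.6
  weight_start: 0.4
- class_code: 3.2.1
  intro_year: 2000
  transform_id: buchwald_hartwig
  weight_end: 1.2
  weight_start: 0.2
- class_code: 10.1.1
  intro_year: null
  transform_id: grignard_ester_single
  weight_end: 0.6
  weight_start: 0.9
- class_code: 10.1.2
  intro_year: null
  transform_id: grignard_ketone_addition
  weight_end: 0.7
  weight_start: 0.8
- class_code: 10.2.1
  intro_year: 2015
  transform_id: grignard_ester_double
  weight_end: 0.8
  weight_start: 0.1
context_decorations:
  C: 1.0
  C#N: 1.0
  C(C)(C)C: 1.0
  C(C)=O: 3.5
  C(F)(F)F: 1.0
  C9CC9: 1.0
  C9CCCC9: 1.0
  C9CCCCC9: 1.0
  CC(C)C: 1.0
  CC9CCCCC9: 1.0
  CCCC: 1.0
  CN: 3.5
  CO: 3.5
  Cl: 3.5
  F: 1.0
  N(C)C: 1.0
  N9CCCC9: 1.0
  N9CCOCC9: 1.0
  OC: 1.0
  OC(C)C: 1.0
  OC(F)(F)F: 1.0
  OCC(C)C: 1.0
  OCC9CC9: 1.0
  OCCOC: 1.0
cross_lab_collab_prob: 0.01
dedupe: true
intra_document_same_class_prob: 0.9
n_documents: 120
n_labs: 40
reactions_per_document:
- 5
- 12
scope_decorations:
  C: 1.0
  C#N: 1.0
  C(C)=O: 3.5
  C(C)C: 1.0
  C(F)(F)F: 1.0
  CC: 1.0
  CCC: 1.0
  CN: 3.5
  CO: 3.5
  Cl: 3.5
  F: 1.0
  N(C)C: 1.0
  OC: 1.0
  OCC: 1.0
seed: 0
substrate_families:
  alcohol:
    decorate: true
    scaffolds:
    - OCc1c({x})cc({y})cc1CN
    - OCCc1c({x})cc({y})c(CN)c1
    - OCCCc1c({x})cc(CN)c({y})c1
  alkyl_bromide:
    decorate: true
    scaffolds:
    - BrCc1c({x})cc({y})cc1
    - BrCCc1c({x})cc({y})cc1C
  aryl_bromide:
    decorate: true
    scaffolds:
    - Brc1c({x})cc({y})cc1Cl
    - Brc1c({x})cc(Cl)cc1{y}
    - Cc1c({y})c(Cl)cc({x})c1Br
    - Brc1c({x})cc(Cl)c({y})n1
  aryl_chloride:
    decorate: true
    scaffolds:
    - Clc1c({x})cc({y})cc1
    - Clc1c({x})cc(C)cc1{y}
    - Cc1c({y})cc({x})cc1Cl
    - Clc1c({x})cc({y})cn1
  aryl_ketone:
    decorate: true
    scaffolds:
    - CC(=O)c1c({x})cc({y})cc1
    - CCC(=O)c1c({x})cc({y})cc1C
  boronic_acid:
    decorate: true
    scaffolds:
    - OB(O)c1c({x})cc({y})cc1
    - OB(O)c1cc({x})cc({y})c1
    - OB(O)c1c({x})cc({y})cn1
  carboxylic_acid:
    decorate: true
    scaffolds:
    - OC(=O)c1c({x})cc({y})cc1
    - OC(=O)Cc1c({x})cc({y})cc1
    - OC(=O)c1c({x})cc({y})cn1
  grignard:
    decorate: false
    scaffolds:
    - C[Mg]Br
    - CC[Mg]Br
    - CCC[Mg]Br
    - CCCC[Mg]Br
  methyl_ester:
    decorate: true
    scaffolds:
    - COC(=O)c1c({x})cc({y})cc1C(C)=O
    - COC(=O)Cc1c({x})cc({y})cc1C(C)=O
  phenol:
    decorate: true
    scaffolds:
    - Oc1c({x})cc({y})cc1CN
    - Oc1c({x})cc(CN)cc1{y}
    - Oc1c({x})cc(CN)c({y})n1
  primary_amine:
    decorate: true
    scaffolds:
    - NCc1c({x})cc({y})cc1CCO
    - NCCc1c({x})cc({y})c(CCO)c1
    - NCc1c({x})cc(CCO)c({y})n1
team_size:
- 2
- 4
uncategorized_prob: 0.02
year_range:
- 1998
- 2022
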