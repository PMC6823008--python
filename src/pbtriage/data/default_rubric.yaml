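# Default Clinical Benefit Score (CBS) rubric.
# One point value per category; the photon-unsafe bonus is an additive
# modifier on top of the planning-constraint choice.  Standard totals
# (no miscellaneous adjustment, no "other" planning points) lie in [0, 65].
version: "1.0"
site:
  exclusive: true
  groups:
    - id: head_and_neck
      label: Head and Neck
      items:
        - {id: nasopharynx, label: Nasopharynx, points: 10}
        - {id: sino_nasal, label: Sino-nasal, points: 10}
        - {id: oral_cavity, label: Oral Cavity, points: 5}
        - {id: salivary_gland, label: Salivary Gland, points: 5}
        - {id: oropharynx, label: Oropharynx, points: 5}
        - {id: hypopharynx, label: Hypopharynx, points: 5}
        - {id: cervical_supraclavicular_only, label: Cervical/Supraclavicular Only, points: 5}
        - {id: larynx, label: Larynx, points: 0}
        - {id: thyroid, label: Thyroid, points: 0}
    - id: esophagus
      label: Esophagus
      items:
        - {id: esophagus_thoracic, label: Thoracic, points: 10}
        - {id: ge_junction, label: GE Junction, points: 10}
        - {id: esophagus_cervical, label: Cervical, points: 5}
    - id: gi
      label: GI
      items:
        - {id: hepato_biliary, label: Hepato-biliary, points: 10}
        - {id: anal, label: Anal, points: 7}
        - {id: gastric_duodenum_pancreas, label: Gastric/Duodenum/Pancreas, points: 5}
        - {id: rectal, label: Rectal, points: 5}
    - id: thoracic
      label: Thoracic
      items:
        - {id: pleura_vertebral_invasion, label: Parietal Pleura/Vertebral Body Invasion, points: 10}
        - {id: mediastinum, label: Mediastinum (including post-operative lung), points: 10}
        - {id: thymus, label: Thymus, points: 10}
        - {id: lung_parenchyma, label: Lung Parenchyma, points: 5}
    - id: breast
      label: Breast
      items:
        - {id: left_breast_regional_with_imn, label: LEFT Breast/CW + Regional LNs (including IMNs), points: 10}
        - {id: left_breast_regional_no_imn, label: LEFT Breast/CW + Regional LNs (excluding IMNs), points: 5}
        - {id: left_whole_breast, label: LEFT Whole Breast/CW Only, points: 3}
        - {id: right_breast_regional_with_imn, label: RIGHT Breast/CW + Regional LNs (including IMNs), points: 5}
        - {id: right_breast_regional_no_imn, label: RIGHT Breast/CW + Regional LNs (excluding IMNs), points: 3}
        - {id: right_whole_breast, label: RIGHT Whole Breast/CW Only, points: 0}
        - {id: partial_breast, label: Partial Breast, points: 0}
    - id: gynecologic
      label: Gynecologic
      items:
        - {id: extended_field_endometrial_cervix, label: Extended Field Endometrial/Cervix, points: 10}
        - {id: vulva_definitive_distal_vagina, label: Vulva (Definitive)/Distal Vagina, points: 7}
        - {id: vulva_postop, label: Vulva (Post-operative), points: 5}
        - {id: endometrial_postop_cervix, label: Endometrial/Post-op Cervix, points: 5}
        - {id: intact_cervix_proximal_vagina, label: Intact Cervix/Proximal Vagina, points: 5}
        - {id: ovarian, label: Ovarian, points: 0}
    - id: male_gu
      label: Male-GU
      items:
        - {id: testis_pa_dogleg, label: Testis (PA/Dog Leg), points: 7}
        - {id: prostate_whole_pelvic, label: Prostate + Whole Pelvic, points: 5}
        - {id: prostate_sv_only, label: Prostate/SV Only, points: 2}
        - {id: bladder, label: Bladder, points: 0}
    - id: cns
      label: CNS
      items:
        - {id: base_of_skull_benign_low_grade, label: Base of skull/Benign/Low-Grade, points: 10}
        - {id: brain_non_gbm, label: Brain, Non-GBM, points: 5}
        - {id: brain_gbm, label: Brain, GBM, points: 0}
    - id: other
      label: Other
      items:
        - {id: retroperitoneum, label: Retroperitoneum, points: 10}
        - {id: bone_soft_tissue_skin, label: Bone/Soft tissue/Skin, points: 0}
retreatment:
  "yes": 10
  "no": 0
# Age 21 is merged into the 10-point band (the published bands are "<21" and
# "22-39", leaving 21 unassigned; descriptive groupings use 21-64).  Adjust
# the band bounds here to configure the other reading.
age_bands:
  - {id: under_21, label: "<21", min: 0, max: 20, points: 15}
  - {id: age_21_39, label: "21-39", min: 21, max: 39, points: 10}
  - {id: age_40_49, label: "40-49", min: 40, max: 49, points: 5}
  - {id: age_50_59, label: "50-59", min: 50, max: 59, points: 3}
  - {id: age_60_plus, label: "60+", min: 60, max: null, points: 0}
trial:
  randomized: 10
  interventional: 6
  registry: 3
  off_protocol: 0
planning:
  primary: 5
  secondary: 10
  other_max: 10
  photon_unsafe_bonus: 5
risk_factors:
  SLE_scleroderma: 5
  IBD: 5
  other_genetic: 5
  HIV: 3
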