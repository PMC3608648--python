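# Carbohydrate-utilization pathway definitions: each pathway is a conjunction
# of term groups; each group is a disjunction of acceptable term ids.  Term
# ids are abstract keys (no external ontology needed); `term_sets` names
# shared backbones referenced from pathways via `requires`.
term_sets:
  emp:  # Embden-Meyerhof-Parnas glycolysis, glucose-6-P -> pyruvate
    - [glucokinase]
    - [glucose6p_isomerase]
    - [phosphofructokinase]
    - [fbp_aldolase]
    - [triosephosphate_isomerase]
    - [gapdh]
    - [phosphoglycerate_kinase]
    - [phosphoglyceromutase]
    - [enolase]
    - [pyruvate_kinase, pyruvate_phosphate_dikinase]  # either converts PEP
  ppp_lower:  # non-oxidative pentose phosphate entry into EMP
    - [transketolase]
    - [transaldolase]
    - [ribulose5p_epimerase]
pathways:
  glucose:
    requires: [emp]
  cellobiose:
    requires: [emp]
    groups:
      # any beta-glucosidase family or a cellobiose phosphorylase
      - [beta_glucosidase_gh1, beta_glucosidase_gh3, beta_glucosidase_gh4,
         beta_glucosidase_gh5, cellobiose_phosphorylase]
  galactose:  # Leloir route, 5-gene cluster, to glucose-6-P
    requires: [emp]
    groups:
      - [galactose_mutarotase]
      - [galactokinase]
      - [galactose1p_uridylyltransferase]
      - [udp_glucose_epimerase]
      - [phosphoglucomutase]
  mannose:
    requires: [emp]
    groups:
      - [mannose6p_isomerase]
  xylose:  # isomerase/kinase (xylAB) into the pentose phosphate pathway
    requires: [emp, ppp_lower]
    groups:
      - [xylose_isomerase]
      - [xylulokinase]
  arabinose:  # 3-gene cluster to D-xylulose-5-P
    requires: [emp, ppp_lower]
    groups:
      - [arabinose_isomerase]
      - [ribulokinase]
      - [ribulose5p_4_epimerase]
  glucuronic_acid:  # 5-gene cluster to glyceraldehyde-3-P + pyruvate
    requires: [emp]
    groups:
      - [uronate_isomerase]
      - [mannonate_oxidoreductase]
      - [mannonate_dehydratase]
      - [kdg_kinase]
      - [kdpg_aldolase]
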