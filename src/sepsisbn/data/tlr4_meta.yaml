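# Metadata sidecar for the TLR4 early-sepsis network (rules in
# tlr4_rules.txt).  Node names must match the rules file verbatim.

# Time delays (in update steps) attached to threshold tags: binding /
# functioning events take 2 steps, early (neutrophil) phagocytosis 1, and
# anti-inflammatory cytokine synthesis 3.
delays:
  B_CL: 2
  Phag_L: 2
  Apop: 2
  T_MAC: 2
  T_TF: 2
  Phag_E: 1
  Anti_inflam: 3

# Node classification: 3 pathogen, 13 host-cell, 19 mediator, 4 outcome,
# 3 other.  The mediator/other split of the non-cell, non-outcome nodes is
# editable here; only the counts are load-checked.  Mediators are the
# druggable mediatory molecules (cytokines, soluble receptors, complement
# factors, adhesion molecules, tissue factor, ROS, and the TLR4 receptor);
# "other" collects the non-molecular nodes: the apoptosis process, the NET
# structures, and P-selectin.
classes:
  pathogen: [Infection, Bacteria, LPS]
  host_cell: [Act-Mon, Act-Mac, Mac-M1, Mac-M2, Act-DC, Act-Neu, Act-NK,
              Act-EC, Act-PLT, CD4T, CD8T, Treg, Bcell]
  mediator: [TLR4, ICAM-1, VCAM-1, E-selectin, TF, C3b, C5a, C5b, ROS,
             TNF-a, IL-1B, IFN-gamma, IL-6, IL-8, IL-12, IL-18, IL-10,
             sTNF-R, IL-1Ra]
  outcome: [Phagocytosis, MAC, Thrombosis, Ang2]
  other: [Apoptosis, NETs, P-selectin]

# Simulations start at the onset of infection: Infection active, everything
# else off.
initial_state:
  Infection: 1

# Clinical-surrogate endpoint nodes with the direction of change that counts
# as beneficial: raising bacterial-clearance readouts, lowering the organ
# dysfunction readouts.
endpoints:
  Phagocytosis: increase
  MAC: increase
  Thrombosis: decrease
  Ang2: decrease

# Nodes perturbed (KO/OE) by the mediator screens: the mediator class.
screen_set: [TLR4, ICAM-1, VCAM-1, E-selectin, TF, C3b, C5a, C5b, ROS,
             TNF-a, IL-1B, IFN-gamma, IL-6, IL-8, IL-12, IL-18, IL-10,
             sTNF-R, IL-1Ra]
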