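# Chemical constants for the polar-lipid pipeline.
#
# Backbone formulas are the fully hydroxylated glycerol+headgroup (or, for
# PI-Cer, sphingoid+headgroup) cores BEFORE esterification: a species formula
# is backbone + sum(fatty acid formulas) - n_acyl * H2O.  Each backbone was
# verified against the LIPID MAPS record named in the comment (composing the
# backbone with the record's acyl chains reproduces the record's published
# molecular formula).
#
# Lyso classes share the diacyl backbone with n_acyl = 1.

classes:
  MGDG:   {n_acyl: 2, backbone: C9H18O8,      quant_adduct: "[M+NH4]+", rule: galactolipid_mono}   # MGDG(16:0/18:1) = C43H80O10
  MGMG:   {n_acyl: 1, backbone: C9H18O8,      quant_adduct: "[M+NH4]+", rule: galactolipid_mono}   # MGMG(16:0) = C25H48O9
  DGDG:   {n_acyl: 2, backbone: C15H28O13,    quant_adduct: "[M+NH4]+", rule: galactolipid_di}     # DGDG(16:0/18:1) = C49H90O15
  DGMG:   {n_acyl: 1, backbone: C15H28O13,    quant_adduct: "[M+NH4]+", rule: galactolipid_di}     # DGMG(16:0) = C31H58O14
  SQDG:   {n_acyl: 2, backbone: C9H18O10S,    quant_adduct: "[M-H]-",   rule: sulfolipid}          # SQDG(16:0/18:1) = C43H80O12S
  SQMG:   {n_acyl: 1, backbone: C9H18O10S,    quant_adduct: "[M-H]-",   rule: sulfolipid}          # SQMG(16:0) = C25H48O11S
  DGTS:   {n_acyl: 2, backbone: C10H21NO5,    quant_adduct: "[M+H]+",   rule: betaine}             # DGTS(16:0/18:1) = C44H83NO7
  MGTS:   {n_acyl: 1, backbone: C10H21NO5,    quant_adduct: "[M+H]+",   rule: betaine}             # DGTS(20:5/0:0) = C30H49NO6
  PC:     {n_acyl: 2, backbone: C8H20NO6P,    quant_adduct: "[M+H]+",   rule: choline}             # PC(16:0/18:1) = C42H82NO8P
  LPC:    {n_acyl: 1, backbone: C8H20NO6P,    quant_adduct: "[M+H]+",   rule: choline}             # LPC(16:0) = C24H50NO7P
  PE:     {n_acyl: 2, backbone: C5H14NO6P,    quant_adduct: "[M+H]+",   rule: ethanolamine}        # PE(16:0/18:1) = C39H76NO8P
  PG:     {n_acyl: 2, backbone: C6H15O8P,     quant_adduct: "[M-H]-",   rule: glycerophosphate}    # PG(16:0/18:1) = C40H77O10P
  PI:     {n_acyl: 2, backbone: C9H19O11P,    quant_adduct: "[M-H]-",   rule: inositol}            # PI(16:0/18:1) = C43H81O13P
  PI-Cer: {n_acyl: 1, backbone: C24H48NO10P,  quant_adduct: "[M-H]-",   rule: inositol_ceramide}   # PI-Cer(d18:1/16:0) = C40H78NO11P; backbone = sphingosine(d18:1) + inositol-phosphate - H2O

# MS/MS diagnostic rules.  Head-group evidence: ions are full ion formulas with
# charge (m/z = mass - charge*electron); losses are neutral formulas measured
# against the precursor.  Chain evidence kinds:
#   carboxylate   -> RCOO- ion per acyl chain (negative mode)
#   acyl74        -> [RCO+74]+ acylium + C3H6O2 ion per chain (positive mode)
#   acid_or_ketene-> neutral loss of RCOOH or R=C=O per chain (positive mode)
#   none          -> class identified at sum-composition level; no chain-level
#                    fragment is diagnostic (PI-Cer)
rules:
  galactolipid_mono:
    headgroup: {adduct: "[M+NH4]+", ions: [], losses: [C6H13NO5]}      # NH3 + anhydrohexose
    chains:    {adduct: "[M+NH4]+", kind: acyl74}
  galactolipid_di:
    headgroup: {adduct: "[M+NH4]+", ions: [], losses: [C12H23NO10]}    # NH3 + 2x anhydrohexose
    chains:    {adduct: "[M+NH4]+", kind: acyl74}
  sulfolipid:
    headgroup: {adduct: "[M-H]-", ions: [{formula: C6H9O7S, charge: -1}], losses: []}   # dehydrated sulfoquinovose anion, 225.0075
    chains:    {adduct: "[M-H]-", kind: carboxylate}
  betaine:
    headgroup: {adduct: "[M+H]+", ions: [{formula: C10H22NO5, charge: 1},   # glyceryl-trimethylhomoserine + H, 236.1493
                                          {formula: C7H14NO2, charge: 1}],  # trimethylhomoserine fragment, 144.1019
                losses: []}
    chains:    {adduct: "[M+H]+", kind: acid_or_ketene}
  choline:
    headgroup: {adduct: "[M+H]+", ions: [{formula: C5H15NO4P, charge: 1}], losses: []}  # phosphocholine, 184.0733
    chains:    {adduct: "[M+CH3COO]-", kind: carboxylate}
  ethanolamine:
    headgroup: {adduct: "[M+H]+", ions: [], losses: [C2H8NO4P]}        # phosphoethanolamine, 141.0191
    chains:    {adduct: "[M-H]-", kind: carboxylate}
  glycerophosphate:
    headgroup: {adduct: "[M-H]-", ions: [{formula: C3H6O5P, charge: -1}], losses: []}   # glycerophosphate - H2O, 152.9958
    chains:    {adduct: "[M-H]-", kind: carboxylate}
  inositol:
    headgroup: {adduct: "[M-H]-", ions: [{formula: C6H10O8P, charge: -1}], losses: []}  # inositol-phosphate - H2O, 241.0119
    chains:    {adduct: "[M-H]-", kind: carboxylate}
  inositol_ceramide:
    headgroup: {adduct: "[M-H]-", ions: [{formula: C6H10O8P, charge: -1}], losses: []}
    chains:    {adduct: "[M-H]-", kind: none}

# Internal standard mix spiked per injection (amounts in ug).  Formulas are the
# published molecular formulas of the Avanti standards.  represents: lipid class
# the standard is chemically matched to (null -> eligible only for the
# closest-retention-time fallback).
internal_standards:
  - {name: dMPC,        represents: PC,     formula: C36H72NO8P,  amount_ug: 0.02,  ion_mode: "+"}
  - {name: dMPE,        represents: PE,     formula: C33H66NO8P,  amount_ug: 0.02,  ion_mode: "+"}
  - {name: SM(d18:1/17:0), represents: null, formula: C40H81N2O6P, amount_ug: 0.02, ion_mode: "+"}
  - {name: LPC(19:0),   represents: LPC,    formula: C27H56NO7P,  amount_ug: 0.02,  ion_mode: "+"}
  - {name: dPPI,        represents: PI,     formula: C41H79O13P,  amount_ug: 0.08,  ion_mode: "-"}
  - {name: dMPG,        represents: PG,     formula: C34H67O10P,  amount_ug: 0.012, ion_mode: "-"}
  - {name: dMPS,        represents: null,   formula: C34H66NO10P, amount_ug: 0.04,  ion_mode: "-"}
  - {name: dMPA,        represents: null,   formula: C31H61O8P,   amount_ug: 0.08,  ion_mode: "-"}
  - {name: C17-Ceramide, represents: PI-Cer, formula: C35H69NO3,  amount_ug: 0.02,  ion_mode: "+"}
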