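# Moiety-composition grouping of 24 nucleotide-containing ligands.
#
# Letter key: R ribose (or ribitol), B nucleobase, P phosphate,
# F flavin (isoalloxazine/deazaflavin), N nicotinamide, S sulfur,
# T thiamine, O other moiety.
#
# The assignment below is a documented default derived from standard
# moiety decomposition of each cofactor; edit or replace the file to
# change memberships (pass the path to load_ligand_groups).
ligands:
  AMP: RBP
  ADP: RBP
  ATP: RBP
  GMP: RBP
  GDP: RBP
  GTP: RBP
  CTP: RBP
  cAMP: RBP
  cGMP: RBP
  c-di-AMP: RBP
  c-di-GMP: RBP
  PAP: RBP               # 3'-phosphoadenosine-5'-phosphate
  CoA: RBPS               # adenosine + phosphates + pantetheine thiol
  PPS: RBPS               # phosphoadenosine phosphosulfate (PAPS)
  Acetyl-CoA: RBPSO       # CoA + acetyl moiety
  SAM: RBSO               # S-adenosylmethionine: no phosphate
  NAD(H): RBPN
  NADP: RBPN
  FAD(H): RBPF
  FMN: RPF                # riboflavin phosphate: ribitol, no nucleobase
  F-420: RPFO             # deazaflavin + ribitol phosphate + lactyl/glutamyl tail
  ThPP: TP                # thiamine pyrophosphate
  THD: TOP
  PLP: OP                 # pyridoxal 5'-phosphate
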