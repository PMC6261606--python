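# Transcription of the L. lactis pyruvate-branch model (14 reactions).
# Reaction numbering follows the published pathway scheme:
#   v1  glycolysis (lumped; Glc + 2 ADP + 2 NAD -> 2 Pyr + 2 ATP + 2 NADH)
#   v2  lactate dehydrogenase          v8  acetolactate synthase (rev. Hill)
#   v3  pyruvate dehydrogenase         v9  acetolactate decarboxylase
#   v4  phosphotransacetylase          v10 acetoin efflux (irreversible)
#   v5  acetate kinase                 v11 acetoin dehydrogenase (rev. bi-bi)
#   v6  acetaldehyde dehydrogenase     v12 ATPase
#   v7  alcohol dehydrogenase          v13 NADH oxidase
#                                      v14 non-enzymatic acetolactate decarb.
# Conserved pairs ATP/ADP (phiA), AcCoA/CoA (phiC) and NADH/NAD (phiN) are
# declared in the RATIOS block.  See docs/fixture-provenance.md for the
# provenance and calibration notes of the kinetic parameters.
MODEL pyruvate_branch
SPECIES
  Pyr 1.0
  Acal 0.05
  Acp 0.5
  Aclac 0.5
  Acet 1.0
  ATP 2.0
  ADP 3.0
  AcCoA 0.2
  CoA 0.8
  NADH 0.3
  NAD 9.7
FIXED
  Glc 25.0
  Lac 0.1
  Ac 1.0
  EtOH 0.1
  But 0.05
  O2 0.2
  Pi 10.0
PARAMETERS
  V1 300.0
  K1Glc 1.0
  K1ADP 0.5
  K1Pyr 20.0
  K1ATP 3.0
  K1NAD 0.2
  K1NADH 0.05
  V2 2000.0
  Keq2 21120.0
  K2Pyr 1.5
  K2NADH 0.08
  K2Lac 100.0
  K2NAD 2.4
  V3 600.0
  K3Pyr 1.0
  K3NAD 0.4
  K3NADH 0.08
  K3CoA 0.014
  K3AcCoA 0.05
  K3i 0.8
  V4 420.0
  Keq4 0.0065
  K4AcCoA 0.2
  K4Pi 2.6
  K4AcP 0.7
  K4CoA 0.029
  V5 2700.0
  Keq5 174.0
  K5AcP 0.16
  K5ADP 0.5
  K5Ac 7.0
  K5ATP 0.07
  V6 97.0
  Keq6 1.0
  K6AcCoA 0.007
  K6NADH 0.025
  K6Acal 10.0
  K6NAD 0.08
  K6CoA 0.008
  V7 162.0
  Keq7 12355.0
  K7Acal 0.03
  K7NADH 0.05
  K7EtOH 1.0
  K7NAD 0.08
  V8 600.0
  Keq8 9.0e12
  K8Pyr 15.0
  K8Aclac 1.0
  h8 2.4
  V9 106.0
  Keq9 9000.0
  K9Aclac 10.0
  K9Acet 100.0
  V10 200.0
  K10Acet 5.0
  V11 105.0
  Keq11 1400.0
  K11Acet 0.06
  K11NADH 0.02
  K11But 2.6
  K11NAD 0.16
  V12 900.0
  K12ATP 6.2
  V13 118.0
  K13NADH 0.041
  K13O2 0.2
  K13NAD 1.0
  k14 0.01
REACTIONS
  v1: Glc + 2 ADP + 2 NAD -> 2 Pyr + 2 ATP + 2 NADH ! core=irrev_mm
  v2: Pyr + NADH = Lac + NAD ! keq=Keq2 core=rev_mm
  v3: Pyr + NAD + CoA -> AcCoA + NADH ! core=irrev_mm
  v4: AcCoA + Pi = Acp + CoA ! keq=Keq4 core=rev_mm
  v5: Acp + ADP = Ac + ATP ! keq=Keq5 core=rev_mm
  v6: AcCoA + NADH = Acal + CoA + NAD ! keq=Keq6 core=rev_mm
  v7: Acal + NADH = EtOH + NAD ! keq=Keq7 core=rev_mm
  v8: 2 Pyr = Aclac ! keq=Keq8 core=rev_hill
  v9: Aclac = Acet ! keq=Keq9 core=rev_mm
  v10: Acet -> ! core=irrev_mm
  v11: Acet + NADH = But + NAD ! keq=Keq11 core=rev_mm
  v12: ATP -> ADP ! core=irrev_mm
  v13: NADH + O2 -> NAD ! core=irrev_mm
  v14: Aclac -> Acet ! core=mass_action
RATES
  v1: V1*(Glc/K1Glc)*(ADP/K1ADP)*(NAD/K1NAD)/((1 + Glc/K1Glc + Pyr/K1Pyr)*(1 + ADP/K1ADP + ATP/K1ATP)*(1 + NAD/K1NAD + NADH/K1NADH))
  v2: V2/(K2Pyr*K2NADH)*(Pyr*NADH - Lac*NAD/Keq2)/((1 + Pyr/K2Pyr + Lac/K2Lac)*(1 + NADH/K2NADH + NAD/K2NAD))
  v3: V3*(Pyr/K3Pyr)*(NAD/K3NAD)*(CoA/K3CoA)/((1 + Pyr/K3Pyr)*(1 + NAD/K3NAD + NADH/K3NADH)*(1 + CoA/K3CoA + AcCoA/K3AcCoA)*(1 + NADH/(NAD*K3i)))
  v4: V4/(K4AcCoA*K4Pi)*(AcCoA*Pi - Acp*CoA/Keq4)/((1 + AcCoA/K4AcCoA + Acp/K4AcP)*(1 + Pi/K4Pi + CoA/K4CoA))
  v5: V5/(K5AcP*K5ADP)*(Acp*ADP - Ac*ATP/Keq5)/((1 + Acp/K5AcP + Ac/K5Ac)*(1 + ADP/K5ADP + ATP/K5ATP))
  v6: V6/(K6AcCoA*K6NADH)*(AcCoA*NADH - Acal*CoA*NAD/Keq6)/((1 + AcCoA/K6AcCoA + Acal/K6Acal + CoA/K6CoA)*(1 + NADH/K6NADH + NAD/K6NAD))
  v7: V7/(K7Acal*K7NADH)*(Acal*NADH - EtOH*NAD/Keq7)/((1 + Acal/K7Acal + EtOH/K7EtOH)*(1 + NADH/K7NADH + NAD/K7NAD))
  v8: V8*(Pyr/K8Pyr)**2*(1 - Aclac/(Pyr**2*Keq8))*(Pyr/K8Pyr + Aclac/K8Aclac)**(h8 - 2)/(1 + (Pyr/K8Pyr + Aclac/K8Aclac)**h8)
  v9: V9/K9Aclac*(Aclac - Acet/Keq9)/(1 + Aclac/K9Aclac + Acet/K9Acet)
  v10: V10*Acet/(K10Acet + Acet)
  v11: V11/(K11Acet*K11NADH)*(Acet*NADH - But*NAD/Keq11)/((1 + Acet/K11Acet + But/K11But)*(1 + NADH/K11NADH + NAD/K11NAD))
  v12: V12*ATP/(K12ATP + ATP)
  v13: V13*(NADH/K13NADH)*(O2/K13O2)/((1 + NADH/K13NADH + NAD/K13NAD)*(1 + O2/K13O2))
  v14: k14*Aclac
RATIOS
  phiA: ATP / ADP
  phiC: AcCoA / CoA
  phiN: NADH / NAD
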