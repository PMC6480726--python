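# Spin-system library for urine/biofluid 1H NMR simulation.
#
# Each metabolite is a list of subsystems (<= 8 expanded spins each; larger
# molecules are split so exact diagonalisation stays cheap). Fields per
# subsystem: labels, shifts_ppm, protons, couplings ([i, j, J_Hz] between
# group indices), t1_s, t2_s.
#
# Chemical shifts are literature urine-condition values (HMDB/BMRB-style
# assignments, pH ~7); the glucose anomeric C1-H shifts and the alanine T1
# values follow the benchtop protocol's reported values. Couplings are
# literature defaults; `source` records provenance per entry. T1 values are
# low-field (60 MHz) estimates: T1 shortens by roughly half between 400 and
# 60 MHz, and the defaults keep 10 s repetition >= 5*T1 except where a long
# T1 is itself the point (alanine alpha-CH).
metabolites:
  tsp:
    name: "TSP (sodium 3-(trimethylsilyl)propionate-d4)"
    source: "reference standard, 9 equivalent Si(CH3)3 protons at 0.00 ppm"
    subsystems:
      - labels: ["Si(CH3)3"]
        shifts_ppm: [0.0]
        protons: [9]
        couplings: []
        t1_s: [1.9]
        t2_s: [1.2]
  glucose_alpha:
    name: "alpha-D-glucose"
    source: "C1-H doublet 5.25 ppm (protocol value), J(1,2) = 3.8 Hz literature; ring protons lumped as uncoupled bulk lines 3.4-3.9 ppm"
    subsystems:
      - labels: ["C1H", "C2H"]
        shifts_ppm: [5.25, 3.54]
        protons: [1, 1]
        couplings: [[0, 1, 3.8]]
        t1_s: [1.2, 1.0]
        t2_s: [0.8, 0.8]
      - labels: ["C3H", "C4H", "C5H", "C6Ha", "C6Hb"]
        shifts_ppm: [3.71, 3.42, 3.83, 3.76, 3.74]
        protons: [1, 1, 1, 1, 1]
        couplings: []
        t1_s: [1.0, 1.0, 1.0, 1.0, 1.0]
        t2_s: [0.8, 0.8, 0.8, 0.8, 0.8]
  glucose_beta:
    name: "beta-D-glucose"
    source: "C1-H doublet 4.65 ppm (protocol value), J(1,2) = 8.0 Hz literature; bulk ring lines 3.2-3.9 ppm"
    subsystems:
      - labels: ["C1H", "C2H"]
        shifts_ppm: [4.65, 3.25]
        protons: [1, 1]
        couplings: [[0, 1, 8.0]]
        t1_s: [1.2, 1.0]
        t2_s: [0.8, 0.8]
      - labels: ["C3H", "C4H", "C5H", "C6Ha", "C6Hb"]
        shifts_ppm: [3.49, 3.40, 3.46, 3.90, 3.72]
        protons: [1, 1, 1, 1, 1]
        couplings: []
        t1_s: [1.0, 1.0, 1.0, 1.0, 1.0]
        t2_s: [0.8, 0.8, 0.8, 0.8, 0.8]
  3_hydroxybutyrate:
    name: "3-D-hydroxybutyrate"
    source: "CH3 doublet 1.20 ppm J = 6.3 Hz to CH 4.16 ppm; CH2 ABX simplified to two lines 2.31/2.41 ppm"
    subsystems:
      - labels: ["CH3", "CH"]
        shifts_ppm: [1.20, 4.16]
        protons: [3, 1]
        couplings: [[0, 1, 6.3]]
        t1_s: [0.9, 1.6]
        t2_s: [0.8, 0.8]
      - labels: ["CH2a", "CH2b"]
        shifts_ppm: [2.31, 2.41]
        protons: [1, 1]
        couplings: [[0, 1, -14.5]]
        t1_s: [0.9, 0.9]
        t2_s: [0.8, 0.8]
  creatinine:
    name: "creatinine"
    source: "two singlets: N-CH3 3.03 ppm, CH2 4.05 ppm (protocol assignment)"
    subsystems:
      - labels: ["NCH3"]
        shifts_ppm: [3.03]
        protons: [3]
        couplings: []
        t1_s: [1.2]
        t2_s: [0.9]
      - labels: ["CH2"]
        shifts_ppm: [4.05]
        protons: [2]
        couplings: []
        t1_s: [1.4]
        t2_s: [0.9]
  citrate:
    name: "citrate"
    source: "AB pair 2.53/2.67 ppm, 2J = 15.1 Hz literature; strongly second-order at 60 MHz"
    subsystems:
      - labels: ["CH2a", "CH2b"]
        shifts_ppm: [2.53, 2.67]
        protons: [2, 2]
        couplings: [[0, 1, -15.1]]
        t1_s: [0.7, 0.7]
        t2_s: [0.6, 0.6]
  lactate:
    name: "lactate"
    source: "CH3 doublet 1.33 ppm, CH quartet 4.13 ppm, J = 6.93 Hz literature"
    subsystems:
      - labels: ["CH3", "CH"]
        shifts_ppm: [1.33, 4.13]
        protons: [3, 1]
        couplings: [[0, 1, 6.93]]
        t1_s: [0.9, 1.8]
        t2_s: [0.8, 0.8]
  alanine:
    name: "alanine"
    source: "CH3 doublet 1.48 ppm, alpha-CH quartet 3.78 ppm, J = 7.26 Hz literature; T1 1.51 s (CH3) and 6.94 s (alpha-CH), protocol-determined"
    subsystems:
      - labels: ["CH3", "aCH"]
        shifts_ppm: [1.48, 3.78]
        protons: [3, 1]
        couplings: [[0, 1, 7.26]]
        t1_s: [1.51, 6.94]
        t2_s: [0.8, 0.8]
  acetone:
    name: "acetone"
    source: "singlet 2.23 ppm, 6 equivalent protons"
    subsystems:
      - labels: ["(CH3)2"]
        shifts_ppm: [2.23]
        protons: [6]
        couplings: []
        t1_s: [1.6]
        t2_s: [1.0]
  acetate:
    name: "acetate"
    source: "singlet 1.92 ppm"
    subsystems:
      - labels: ["CH3"]
        shifts_ppm: [1.92]
        protons: [3]
        couplings: []
        t1_s: [1.5]
        t2_s: [1.0]
  n_acetyl:
    name: "N-acetyl storage compounds"
    source: "composite N-acetyl singlet 2.04 ppm"
    subsystems:
      - labels: ["NAc-CH3"]
        shifts_ppm: [2.04]
        protons: [3]
        couplings: []
        t1_s: [1.0]
        t2_s: [0.8]
  hippurate:
    name: "hippurate"
    source: "aromatic ring d 7.84 (2H), t 7.55 (2H), t 7.64 (1H), J(ortho) ~7.6 Hz literature; alpha-CH2 singlet 3.96 ppm"
    subsystems:
      - labels: ["H2,6", "H3,5", "H4"]
        shifts_ppm: [7.84, 7.55, 7.64]
        protons: [2, 2, 1]
        couplings: [[0, 1, 7.7], [1, 2, 7.4]]
        t1_s: [1.8, 1.8, 1.8]
        t2_s: [0.9, 0.9, 0.9]
      - labels: ["aCH2"]
        shifts_ppm: [3.96]
        protons: [2]
        couplings: []
        t1_s: [0.9]
        t2_s: [0.8]
  indoxyl_sulfate:
    name: "indoxyl sulphate"
    source: "indole ring lines 7.19/7.27 (t), 7.36 (s), 7.50/7.70 (d), simplified to uncoupled lines"
    subsystems:
      - labels: ["H5", "H6", "H2", "H7", "H4"]
        shifts_ppm: [7.19, 7.27, 7.36, 7.50, 7.70]
        protons: [1, 1, 1, 1, 1]
        couplings: []
        t1_s: [1.8, 1.8, 1.8, 1.8, 1.8]
        t2_s: [0.9, 0.9, 0.9, 0.9, 0.9]
  methylsuccinate:
    name: "methylsuccinate"
    source: "CH3 doublet 1.08 ppm J = 7.2 Hz to CH 2.85 ppm (CH2 omitted: falls in an excluded region)"
    subsystems:
      - labels: ["CH3", "CH"]
        shifts_ppm: [1.08, 2.85]
        protons: [3, 1]
        couplings: [[0, 1, 7.2]]
        t1_s: [0.9, 1.2]
        t2_s: [0.8, 0.8]
  formate:
    name: "formate"
    source: "singlet 8.46 ppm"
    subsystems:
      - labels: ["HCOO"]
        shifts_ppm: [8.46]
        protons: [1]
        couplings: []
        t1_s: [1.9]
        t2_s: [1.2]
  ethanol:
    name: "ethanol"
    source: "CH3 triplet 1.19 ppm, CH2 quartet 3.66 ppm, J = 7.07 Hz (protocol value)"
    subsystems:
      - labels: ["CH3", "CH2"]
        shifts_ppm: [1.19, 3.66]
        protons: [3, 2]
        couplings: [[0, 1, 7.07]]
        t1_s: [1.8, 1.8]
        t2_s: [1.0, 1.0]
  glycine:
    name: "glycine"
    source: "singlet 3.56 ppm; fixed urine background"
    subsystems:
      - labels: ["CH2"]
        shifts_ppm: [3.56]
        protons: [2]
        couplings: []
        t1_s: [1.3]
        t2_s: [0.9]
  tmao:
    name: "trimethylamine N-oxide"
    source: "singlet 3.27 ppm; fixed urine background"
    subsystems:
      - labels: ["N(CH3)3"]
        shifts_ppm: [3.27]
        protons: [9]
        couplings: []
        t1_s: [1.2]
        t2_s: [0.9]

# Composite analytes: a mixture of library entries with molar fractions.
composites:
  glucose:
    note: "equilibrium anomer mixture: 36% alpha / 64% beta (mutarotation equilibrium used by the quantification protocol)"
    components:
      glucose_alpha: 0.36
      glucose_beta: 0.64
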