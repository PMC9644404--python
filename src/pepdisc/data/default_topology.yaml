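# Default topology map for the synthetic nanodisc systems.
# molecule_blocks describe the bead order of coordinate files written by
# the generator: 200 DMPC-like 10-bead lipids, 28 peptides of the 22A
# variant (22 backbone + 8 charged side-chain beads), one 50-bead LCAT body.
peptide_sequences:
  22A: PVLDLFRELLNELLEALKQKLK
  22A-K: PVLDLFRELLNELLEALKQKL
  22A-K22Q: PVLDLFRELLNELLEALKQKLQ
  22A-R7Q: PVLDLFQELLNELLEALKQKLK
lcat_landmarks:
  pose_center: [CYS, 31]
  pose_tip: [ILE, 326]
  roll_reference: [GLY, 308]
  siteA_anchor_1: [PRO, 232]
  siteA_anchor_2: [TRP, 48]
bead_size_assignment:
  BB: regular
  SC1: small
  NC3: regular
  PO4: regular
  GL1: small
  GL2: small
  C1A: regular
  C2A: regular
  C3A: regular
  C1B: regular
  C2B: regular
  C3B: regular
molecule_blocks:
  - name: DMPC
    molecule_type: lipid
    count: 200
    beads_per_molecule: 10
  - name: 22A
    molecule_type: peptide
    count: 28
    beads_per_molecule: 30
  - name: LCAT
    molecule_type: lcat
    count: 1
    beads_per_molecule: 50
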