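# Catalytic-loop dynamics analysis of a trajectory.
# aaad loop run examples/loop_run.yaml
seed: 1
output_dir: loop_out
input:
  topology: dimer.pdb
  trajectory: dimer.xtc
  allow_missing_parameters: true   # no LJ terms needed for loop metrics
loop:
  align_selection: "name CA"       # dimer principal axes -> z
  theta:
    anchor: "name CA and resid 342"
    tip: "name CA and resid 348"
    loop: "name CA and resid 342-361"
    closed_reference: closed_model.pdb   # loop-closed structure for z_ref
  contact_a: "resid 348"
  contact_b: "resid 203"
  helix_range: [342, 361]          # null for Calpha-only input
  fit_selection: "name CA and not resid 342-361"   # core fit for PCA/RMSD
  cluster_cutoff: 6.2
  pca_bins: 50
  temperature: 300.0
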