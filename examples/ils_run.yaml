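# O2-accessibility analysis of a trajectory.
# aaad ils run examples/ils_run.yaml
seed: 1
output_dir: ils_out
input:
  topology: system.pdb          # PDB with CRYST1 (orthorhombic)
  trajectory: system.dcd        # DCD/XTC/multi-model PDB
  parameters: params.csv        # residue_name,atom_name,rmin_half,epsilon,charge
ils:
  temperature: 300.0
  grid_spacing: 1.0
  cutoff: 10.0
  orientation_count: 21
  frame_stride: 1
bulk:
  min_distance_from_solute: 12.0
sites:                          # one entry per active site / monomer
  - name: monomerA
    position: [45.0, 38.0, 52.0]   # Å, e.g. the PLP C4' position
    isovalue: 3.9                  # channel isosurface level, kcal/mol
    group: WT
    form: apo
    replica: 0
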