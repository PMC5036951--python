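# Fidelity-scale pipeline settings emulating the clinical acquisition:
# 0.39 x 0.39 mm in-plane, 3 mm slices, factor-7 through-plane interpolation
# to ~0.43 mm. Slow; the test suite exercises the coarse demo defaults
# instead. Run with:  hippoflat run-all --config configs/fidelity.yaml
seed: 1
out_dir: results/pipeline_fidelity
shape_kind: folded_c_sheet
grid_dims: [64, 64, 19]
voxel_spacing_mm: [0.39, 0.39, 3.0]
interpolation_factor: 7
n_subjects_imaging: 54
layer_connectivity: face
geodesic_connectivity: face+edge+corner
n_landmarks: 500
pixel_size_mm: 0.4
thickness_convention: boundary_corrected
alpha: 0.05
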