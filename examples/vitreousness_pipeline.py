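"""Kernel vitreousness from a hyperspectral scene, end to end.

Simulates a noisy scene whose kernels grade from a glassy core to a mealy
rim, runs background masking, endmember extraction, NNLS unmixing, tissue
classification and the kernel-level index V = (N_g + 0.5 N_i) / N_total,
then compares against the planted per-kernel truth.
"""

import numpy as np

import kernelpheno as kp

ph = kp.make_kernel_scene(layout=(3, 3), image_shape=(120, 120), bands=200,
                          abundance_pattern="radial_gradient", snr_db=30,
                          seed=1)
mask = kp.background_mask(ph.cube)
labels = kp.label_kernels(mask, expected=(3, 3))
em = kp.extract_endmembers(ph.cube, mask, n_em=3, seed=1)
ab, _ = kp.nnls_unmix(ph.cube, mask, em)
assign = kp.assign_tissue_classes(em, ab, kernel_mask=mask.valid)
classes = kp.classify_pixels(ab, assign)
records = kp.kernel_records(classes, labels, cultivar="phantom")

print(kp.vitreousness.records_table(records).to_string(index=False))
mean_v, sd_v = np.mean([r.v for r in records]), np.std([r.v for r in records], ddof=1)
print(f"\ncultivar mean V = {mean_v:.3f} +- {sd_v:.3f}"
      f"   (planted mean {ph.true_v.mean():.3f})")
# Each row counts glassy/intermediate/mealy pixels inside one kernel; V
# weights intermediate tissue by one half.  At 30 dB the recovered V stays
# within a few hundredths of the planted value.
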