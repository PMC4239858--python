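"""How voxel size, window width and median filtering bias adipose readouts.

Builds a cohort whose fat sits in fine structures (a surface shell and
0.25 mm marbled strands), then refits measured-vs-true adipose mass for every
combination of reconstruction voxel (125/250/500 um, by mean-pool
resampling), segmentation window ([-300,-50) vs [-200,-50) HU) and 1 mm
median filtering.

Expected directions: the 500 um slope drops below the 125 um slope (fine fat
is partial-volume diluted out of the window), the narrow window never
measures more than the wide one, and the median filter shifts the intercept
down (it erodes thin depots) while leaving linearity intact.
"""

from ctcomp import make_thin_shell_cohort, run_parameter_sweep

cohort = make_thin_shell_cohort(4, seed=29, edge_um=125.0, noise_sd_hu=20.0)
print("true adipose (g):", [round(t.masses_g["adipose"], 2) for _, t in cohort])

table = run_parameter_sweep(cohort, reference=None)
cols = ["edge_um", "window_lo", "window_hi", "median_mm", "slope", "intercept", "r_squared"]
print(table[cols].round(4).to_string(index=False))
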