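"""Detect hyperreflective opacities and classify them by size.

Background speckle inside the vitreous mask is suppressed with a robust
median + 6·sigma_MAD threshold; surviving connected components become
opacity records with area, intensity, eccentricity and orientation, and are
binned into the activation-state taxonomy (<10, 10-50, 50-250, >250 um^2).
"""

from octvit import (
    AnalysisParams,
    PhantomConfig,
    analyze_stack,
    generate_phantom,
    write_feature_table,
)

config = PhantomConfig(
    n_frames=2,
    class_counts={"non_activated": 8, "activated": 6, "complex": 3},
    seed=3,
)
stack, truth = generate_phantom(config)

analysis = analyze_stack(stack, AnalysisParams(min_area_px=2))
s = analysis.summary
print(f"detected opacities: {s.n_opacities} (injected: {len(truth.blobs)})")
print(f"mean per B-scan:    {s.mean_n_opacities:.1f}")
print(f"total cell area:    {s.total_area_um2:.1f} um^2")
print(f"mean opacity area:  {s.mean_area_um2:.1f} um^2")
print("class percentages: ", {c: round(p, 1) for c, p in s.class_percent.items()})
print("class mean ecc:    ", {c: round(e, 2) for c, e in s.class_mean_eccentricity.items()})

write_feature_table(analysis.records, "scratch_opacities.csv",
                    eye_meta={"animal": "demo", "cohort": "MsDx", "eye": "RE", "week": 4})
print("per-opacity table written to scratch_opacities.csv")
# With min_area_px=2 the detector reports exactly the injected >=2 px blobs;
# at min_area_px=1 rare single-pixel speckle exceedances would also appear.
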