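"""4C-seq pipeline on simulated libraries: dosage-dependent insulation.

Simulates six 4C libraries (two donors per CNV genotype) under a
distance-decay contact model where an insulator downstream of the
viewpoint attenuates crossing contacts per Dup allele, then runs the full
pipeline: fragment filtering, per-end read counts, 30-fragment smoothing,
+/-2 Mb normalization, and the downstream-fraction quantification.
"""

from ooadrift.fourc import (
    contact_asymmetry,
    genotype_trend,
    normalize_profile,
    reads_to_profile,
    smooth_profile,
)
from ooadrift.synth import FourCSimConfig, simulate_4c

cfg = FourCSimConfig(seed=7)  # dosages (0, 0, 1, 1, 2, 2)
full_map, valid_map, params, samples = simulate_4c(cfg)
print(f"fragments: {len(full_map.fragments)} digested, {len(valid_map.fragments)} valid")

results = []
for s in samples:
    prof = reads_to_profile(s.read_starts, valid_map)
    prof = smooth_profile(prof, params.smoothing_window_fragments)
    prof = normalize_profile(prof, params.viewpoint, params.normalization_halfwidth_bp)
    a = contact_asymmetry(prof, dosage=s.dosage)
    results.append(a)
    print(f"  dosage {s.dosage}: downstream fraction {a.fraction_downstream:.3f}")
# More Dup copies -> stronger insulation -> smaller share of contacts
# downstream of the viewpoint (the Sin/Sin > Dup/Sin > Dup/Dup ordering).

trend = genotype_trend(results)
print(f"Spearman rho(dosage, downstream) = {trend.rho:.3f}, "
      f"p = {trend.pvalue:.4f} ({trend.method})")
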