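"""Worked example 5: HEIDI calibration under the pleiotropy null.

Under a single shared causal variant the HEIDI test should reject at its
retention threshold (p <= 0.01) about 1% of the time.  This short run uses
100 seeded loci for speed; scripts/acceptance.py runs the full 500-locus
version used for the acceptance target.
"""

from mirsmr import SimConfig, run_heidi, select_top_instrument, simulate_scenario

n_reps, threshold = 100, 0.01
rejected = tested = 0
for i in range(n_reps):
    sc = simulate_scenario(SimConfig(seed=7000 + i, model="pleiotropy"))
    locus = sc.to_locus()
    top = select_top_instrument(locus)
    res = run_heidi(locus, top)
    if res.status != "tested":
        continue
    tested += 1
    rejected += res.p_heidi <= threshold

print(f"tested {tested} of {n_reps} simulated null loci")
print(f"rejection fraction at p <= {threshold}: {rejected / tested:.3f} "
      f"(nominal {threshold})")
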