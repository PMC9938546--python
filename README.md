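# immunoscreen

Analysis toolkit for plate-based tumor–immune co-culture drug screens.

In this assay format, GFP-labeled cancer cells (e.g. HCT116-GFP) are grown in
384-well plates either alone or co-cultured with anti-CD3/IL2-activated
peripheral blood mononuclear cells (PBMCs), compounds are added at a single
screening dose (10 µM), and per-well GFP intensity is read every 4 h for 96 h
as a proxy for surviving cancer cells. The scientific question is which
compounds *potentiate immune-mediated killing* — reduce co-culture viability
beyond what their direct cytotoxicity explains. `immunoscreen` is for screen
analysts and computational biologists who need the full chain from raw
plate tables to ranked hits, plus a simulator to validate the chain's
operating characteristics.

## What it computes

**Assay quality.** Per timepoint, two Z-factors on untreated control wells,
each of the form Z = 1 − 3(σ₁ + σ₂)/|μ₁ − μ₂|:

- Z_M (immunomodulation): cancer monoculture vs PBMC monoculture — the
  assay's dynamic range;
- Z_P (immunopotentiation): co-culture vs PBMC monoculture — the window left
  for detecting enhanced killing.

Standard categories apply: 1 ideal, [0.5, 1) excellent, [0, 0.5) marginal,
negative = overlapping controls.

**Viability.** Percent-of-control: treated-well signal divided by the
control-well mean, per culture type (or, for synergy scoring, everything
relative to the untreated cancer monoculture).

**Bliss immunopotentiation score.** Treating activated PBMCs as a second
"drug", with all viabilities relative to untreated monoculture:

    B = V_drug(mono) · V_PBMC − V_drug+PBMC(co-culture)

B > 0 means the combination kills more than independent action predicts —
the compound potentiates immune killing. Compounds are ranked by descending
B (ties: lower combination viability, then compound id).

**DEG set logic.** On gene × condition signed linear fold-change tables:
thresholding (|FC| ≥ 2 by default), common/unique gene sets with
direction-aware semantics, and 2–3-way Venn region counts.

**Simulator.** Logistic cancer growth (rate r, capacity K) minus first-order
kill terms — Hill-shaped direct drug kill and a donor-modulated immune kill
rate that compounds can potentiate — with multiplicative lognormal
measurement noise. Calibrated so untreated co-culture viability at 72 h is
~50–55% of monoculture. A planted-potentiator layer measures the
sensitivity/false-discovery of top-N hit calling.

## Worked example

```python
import immunoscreen as im

# a 3-donor control plate: 64 untreated wells per culture group, 5% CV
config = im.SimulationConfig(seed=1, noise_cv=0.05)
plates = im.simulate_plateset(
    config, im.make_control_layout(64, donors=("D1", "D2", "D3"))
)

profile = im.qc_profile(plates)
print(f"min Z_M = {min(profile.z_m):.3f}")          # min Z_M = 0.817

records = im.compute_viability(plates, time=72.0, baseline="MONOCULTURE")
per_donor = [
    sum(r.viability for r in records
        if r.donor_id == d and r.culture == im.Culture.COCULTURE) /
    sum(1 for r in records
        if r.donor_id == d and r.culture == im.Culture.COCULTURE)
    for d in ("D1", "D2", "D3")
]
mean, pct = im.mean_donor_viability(per_donor)
print(f"PBMC effect: {pct}% of monoculture")        # PBMC effect: 55% of monoculture

print(f"B = {im.bliss_score(0.28, 0.55, 0.11):.3f}")  # B = 0.044
```

The minimum Z_M of 0.817 says the cancer-vs-PBMC signal windows stay in the
"excellent assay" band at every timepoint. The untreated co-culture sits at
55% of monoculture viability — the activated PBMCs' single-agent effect.
The last line scores a compound that reduces monoculture viability to 28%
and co-culture viability to 11% when the PBMC effect alone is 55%:
B = 0.28·0.55 − 0.11 = 0.044 > 0, i.e. the combination is more lethal than
independence predicts.

The same stages are available from the shell:

```bash
immunoscreen simulate --seed 1 --n-compounds 320 \
    --out-map map.csv --out-signals signals.csv
immunoscreen qc --map map.csv --signals signals.csv
immunoscreen score --map map.csv --signals signals.csv --top-n 25
immunoscreen run --simulate --seed 1 --out-dir results/
```

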