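# stoichcal

Stoichiometric CT-number calibration and calibration-table auditing for
radiotherapy treatment planning.

Radiotherapy dose calculation converts each CT voxel's Hounsfield value
(HU) into mass density (MD, g/cm³) or relative electron density (RED,
ρe/(ρe)w) through a calibration table registered in the treatment planning
system (RTPS). `stoichcal` implements a *stoichiometric* calibration: instead
of scanning a rack of tissue substitutes, it scans a few well-characterized
materials, fits an attenuation model, and predicts the theoretical CT
numbers of standard human tissues — which lets a third party audit an
institution's registered table with a small postal phantom carrying only
lung- and bone-equivalent inserts plus a water reference.

## The model

A mixture's linear attenuation coefficient relative to water is
parameterized by two coefficients acting on fixed powers of atomic number
(incoherent ~ Z, coherent ~ Z^2.86, photoelectric ~ Z^4.62):

```
μ/μ_w(k₁,k₂) = (ρ/ρ_w) · Σᵢ (wᵢ/Aᵢ)(Zᵢ + Zᵢ^2.86 k₁ + Zᵢ^4.62 k₂)
               ─────────────────────────────────────────────────────
               (w_H/A_H)(1 + k₁ + k₂) + (w_O/A_O)(8 + 8^2.86 k₁ + 8^4.62 k₂)
```

The conventional calibration maps this to CT numbers as
H = 1000·(μ/μ_w − 1), which pins air at −1000 HU. Real scanners measure
air inside a phantom anywhere from −1100 to −920 HU, so `stoichcal` adds
an empirical scale parameter α:

```
H = 1000·α·(μ/μ_w − 1)
```

Water still maps to exactly 0 HU for any α, while air maps to ≈ −1000·α.
(k₁, k₂, α) are found by least squares in μ/μ_w space from measured CT
numbers, starting at (1.24×10⁻³, 3.06×10⁻⁵, 1.0). Theoretical CT numbers
for eleven bundled representative tissues (ICRP-110-derived, from air at
ρ = 0.001 to hydroxyapatite at ρ = 3.156 g/cm³) then yield CT-MD and
CT-RED tables, and an audit compares those against the RTPS-registered
table per tissue-type density band:

| band | MD range (g/cm³) | tolerance (2% dose) | tolerance (1.4% dose) |
|---|---|---|---|
| lung | 0.2–0.8 | ±0.044 | ±0.031 |
| adipose/muscle | 0.9–1.07 | ±0.022 | ±0.015 |
| cartilage/spongy-bone | 1.07–1.25 | ±0.044 | ±0.031 |

A band **fails** when its mean difference exceeds the tolerance level; the
measured water CT number must additionally sit within 0 ± 5 HU.

## Worked example

Simulate a scan of the audit phantom (150 × 150 mm water-equivalent body
with 20-mm tough-lung, tough-bone, and water inserts) on a virtual scanner
whose air scale is 3 % off nominal, fit the model, build tables, and
self-audit:

```sh
stoichcal simulate --alpha 0.97 --noise-sd 0 \
    --out-image scan.csv --out-measurements meas.csv
stoichcal fit --measurements meas.csv --report fit.json
stoichcal tables --fit-report fit.json --out-md md.csv --out-red red.csv
stoichcal audit --rtps red.csv --measurements meas.csv --report audit.json
```

`meas.csv` contains the ROI means of the three inserts
(`tough_lung,-643.676`, `tough_bone,721.18`, `water,0.0`); the fit report
shows the recovered parameters

```json
"params": {"k1": 0.001190, "k2": 3.075e-05, "alpha": 0.970115}
```

— α is recovered to ~10⁻⁴ from just two informative materials (water is
excluded automatically since its CT number is parameter-independent), while
k₁ and k₂ individually are under-determined (`"identifiable": false`) yet
predict the fitted materials exactly. The audit report then shows every
band with `"verdict": "pass"` and mean differences at the 10⁻⁵ level.

The same steps run in Python via `stoichcal.simulate_image`,
`stoichcal.fit_three_param`, `stoichcal.build_tables`, and
`stoichcal.run_audit`.

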