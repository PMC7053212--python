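# augerdose

Macro-to-microscale internal dosimetry for Auger-electron
radiopharmaceutical therapy, built around ¹²⁵I-labelled PSMA-targeting
small molecules in mouse models of prostate cancer.

¹²⁵I decays by electron capture and emits, per decay, about 19.2 keV as a
cascade of Auger and internal-conversion electrons (ranges < ~20 µm in
tissue) and 42.8 keV as Te K/L X-rays plus a 35.5 keV gamma. The therapeutic
question is geometric: tumor cells internalize the PSMA ligand to the
perinuclear region, so a large share of the electron energy reaches the
nucleus, while kidney proximal-tubule cells bind it only on their apical
(luminal) surface, several micrometres from their nuclei. An organ-level
absorbed dose therefore wildly overstates the biologically relevant dose to
renal cell nuclei. `augerdose` quantifies this, from biodistribution tables
down to nucleus-scale energy deposition.

## What it computes

* **Biokinetics** — %ID/g biodistribution tables → hybrid
  trapezoid + mono-exponential time-activity curves (tail = earliest suffix
  with log-linear R² ≥ 0.9) → time-integrated activity coefficients
  (MBq·h/g per MBq injected), with physical-decay handling for
  decay-corrected data.
* **Organ dose (MIRD schema)** — electron-channel coefficients
  (organ absorbed fraction 1 for sub-cellular-range electrons) and
  photon-channel self-dose coefficients, reported separately:
  `d_e = TIAC × Δ_e / m`, `d_γ = d_e × (Δ_γ/Δ_e) × φ_γ`.
* **Photon transport** — analog Monte Carlo (photoelectric + Klein–Nishina
  Compton in water) for self-absorbed fractions of unit-density spheres
  (0.001–100 g) and a mouse-scaled ellipsoidal kidney, and the power-law
  fit `AF[%] = a·m^b` used for tumor photon dose at arbitrary mass.
* **Cellular microdosimetry** — straight-track continuous-slowing-down
  electron transport in a concentric-sphere cell (26 µm cell, 18 µm
  nucleus): nuclear energy-deposition fractions φ(nucleus ← perinuclear /
  membrane / cytoplasm), combined with the measured subcellular source
  distribution (15/35/50%) into the nucleus-to-average dose ratio
  `Σ fᵢ φᵢ / w_nuc`.
* **Nephron microdosimetry** — annular proximal-tubule model (15 µm lumen,
  10 µm wall, 5 µm mid-wall nuclei): energy partition of apical-surface vs
  internalized decays among nucleus / cytoplasm / lumen, the
  proximal-tubule nuclei dose, glomerular (photon-only) dose, and
  worst-case salivary striated-duct dose.
* **Synthetic data** — uptake × biexponential kinetics with lognormal
  measurement noise and closed-form ground-truth TIACs, emulating the study
  conditions (sustained 2–3:1 tumor:kidney ratio, kidney clearing
  12.8 → 0.2 %ID/g between weeks 2 and 12), so the whole pipeline is
  testable without any external data.

## Worked example

```bash
augerdose report --out report/
```

runs the full analysis on the packaged synthetic study (seeded, fully
deterministic) and prints:

```
| organ     | electron Gy/MBq | photon Gy/MBq | electron Gy | photon Gy |
|-----------|-----------------|---------------|-------------|-----------|
| flu_tumor | 0.00644         | 0.00123       | 0.715       | 0.137     |
| kidney    | 1.12            | 0.154         | 125         | 17.1      |
| pip_tumor | 2.38            | 0.543         | 264         | 60.3      |
| salivary  | 0.0145          | 0.000388      | 1.61        | 0.0431    |

AF[%] = 10.2 * m[g]^0.255  (R^2 = 0.9957)

Cell nuclear dose ratio: 0.307
Tumor nuclear dose: 81.1 Gy
Tubule nuclei dose: 5.91 Gy
Tumor-nucleus : tubule-nucleus dose ratio: 13.7
```

Reading: at 111 MBq injected, the PSMA-positive tumor receives ~264 Gy from
electrons of which ~31% reaches tumor-cell nuclei (~81 Gy), because the
ligand is internalized. The kidney receives a comparable organ-level
electron dose (~125 Gy), but with apical-surface binding only ~1.6% of the
tubule-emitted energy reaches epithelial nuclei, so the nucleus-level
kidney dose collapses to a few Gy — the geometric sparing mechanism that
lets an activity this high be tolerated. The power law summarizes photon
self-absorption versus target mass; its exponent (~0.25) matches the
GEANT4-derived value reported for this system.

Individual stages are available as subcommands (`simulate`, `fit-tac`,
`organ-dose`, `photon-af`, `cell-dose`, `nephron-dose`) and as plain
library functions (see module docstrings).

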