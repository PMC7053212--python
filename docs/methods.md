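# Methods

This note records the models behind `augerdose`, the parameter choices that
matter, and the limits of what the packaged synthetic studies can show.

## Source term

¹²⁵I electron-capture decay is represented by a grouped line spectrum:
seven electron groups (sub-keV N/M Augers, ~3 keV L Augers, the 3.68 keV K
conversion line, ~23 keV K Augers, and the 30.6/34.9 keV L/M⁺ conversion
lines) and five photon groups (Te L and K X-rays, 35.5 keV gamma). Group
yields are scaled by one factor per particle type so the per-decay energies
equal the ICRP 107 aggregates exactly: 19.2 keV (electrons) and 42.8 keV
(photons). Physical half-life 59 d. The grouping matters only for
micro-scale fractions and for photon transport, where the soft Te X-rays
absorb very differently from a 42.8 keV-equivalent line; both a "grouped"
and a "single-line" mode exist, grouped being the default (the power-law
exponent b ≈ 0.255 obtained with grouped lines matches the reported 0.254,
whereas a single 42.8 keV line gives ≈ 0.35).

## Electron transport

Electrons are transported as straight continuous-slowing-down tracks using
Cole's empirical range–energy relation for unit-density matter,
`R[µm] = 0.0431·((E[keV]+0.367)^1.77 − 0.367^1.77)` — the published
constant offset (−0.007 µm) is replaced by the exact value at E = 0 so that
R(0) = 0 and the relation is strictly monotone; the change is below a
nanometre. The residual energy after path s inverts the same relation, so
energy bookkeeping along a track is analytic and exact. Because Cole's
ranges derive from measured penetration depths, using them as straight-line
penetration already folds in some track tortuosity; no separate detour
factor is applied.

Two integration backends share this kernel: a seeded Monte Carlo (isotropic
directions, volume-uniform source radii) and a deterministic Gauss–Legendre
quadrature over emission angle and source radius (256 × 64 nodes). They
agree to ≲0.1% and serve as mutual checks; the deterministic backend
reports zero standard error.

## Photon transport

Analog Monte Carlo in liquid water (the tissue surrogate throughout):
photoelectric absorption and incoherent scattering, coherent scattering
excluded from the transport coefficient (it deposits no energy and barely
deflects at 27–45 keV). The incoherent cross section is analytic
Klein–Nishina on 3.343×10²³ electrons/g; the photoelectric coefficient is
inferred from the embedded NIST water µ_en table by subtracting the
Klein–Nishina energy-transfer part, which keeps absorbed energy consistent
with the tabulated energy-absorption coefficient by construction. Scatter
angles are rejection-sampled from the Klein–Nishina distribution; energy
transferred to electrons is deposited at the interaction point (electron
ranges are negligible against millimetre phantoms); photons below 2 keV
deposit locally. Phantoms: spheres of 0.001–100 g and a kidney ellipsoid
with MIRD-style axis ratios (4.5 : 1.5 : 5.5) scaled to 0.298 g (the
mouse-scaled kidney mass). Absorbed fractions carry per-history standard
errors; the AF(m) power law is fit by log-log least squares with R² on the
fitted scale.

## Cellular model

Concentric spheres: cell 26 µm, nucleus 18 µm (nuclear volume fraction
(18/26)³ = 33.2%). Source compartments: *perinuclear* — isotropic emission
from the nuclear surface itself (a shell standoff would cut off the sub-keV
Auger contribution discontinuously; placing the source on the envelope is
the choice most consistent with the reported 38% deposition fraction);
*membrane* — the 26 µm cell surface; *cytoplasm* — volume-uniform between
nucleus and membrane. Default source distribution 15% perinuclear / 35%
membrane / 50% cytoplasm (the measured subcellular localization in
PSMA-positive tumor cells). Computed nuclear deposition fractions with the
default spectrum: perinuclear ≈ 0.343, cytoplasm ≈ 0.070, membrane ≈ 0.043
(reported values: 0.38 / 0.08 / 0.05; the differences are within the
spectrum-grouping and source-placement freedom, and the ordering —
perinuclear > cytoplasm > membrane — is the robust feature). The
nucleus-to-average dose ratio is `Σ fᵢ φᵢ / w_nuc`; with the *reported*
fractions it evaluates to 34.5% ("35%"), with the package's own transport
to ≈ 31%.

## Nephron model

Infinite annular cylinder: lumen radius 15 µm (typical murine proximal
tubule; not fixed by the source data, configurable), wall 10 µm, nuclei as
5 µm spheres centred mid-wall. Nuclei are not placed explicitly: the energy
crossing the 5 µm mid-wall band is multiplied by the band's nuclear volume
fraction (0.131 for one nucleus per 10 µm × 10 µm epithelial cell
footprint). An explicit nuclei lattice was not implemented; the packing
average is the production estimator and its main error — ignoring intra-band
source–nucleus correlations — is second-order for surface sources 2.5 µm
away from the band. Sources: apical ("surface", on the luminal wall,
matching apical PSMA expression without internalization) or wall-uniform
("cytoplasm").

With the default geometry, apical-surface decays deposit ≈ 1.6% of their
energy in nuclei, ≈ 47% in wall cytoplasm, ≈ 45% in the lumen. The reported
values are 0.8% (nucleus) and 34% (cytoplasm, remainder in lumen). The
nucleus fraction is reproduced within its geometric freedom (lumen radius,
cell size and nuclear packing are not fixed by the source data). The
cytoplasm/lumen split is not: an isotropic source *on* the luminal surface
necessarily sends half its energy inward at these ranges, so a ~65% lumen
share is unreachable in any simple annulus; a brush-border standoff of the
source into the lumen would be needed. This does not affect the nucleus
fraction materially and is left as a known model difference.

### Substructure doses

The proximal-tubule nuclei dose rescales the whole-kidney electron dose by
`φ(nucleus←source) / w_nuc`, with `w_nuc = 0.33` by default — the
*cellular* nuclear mass fraction (same convention as the tumor-cell scale),
which is the normalization under which the reported endpoint (~2 Gy at
111 MBq from a 0.71 Gy/MBq kidney coefficient and φ = 0.008) is internally
consistent. The geometric nuclei-to-wall packing (≈ 0.065) is *not* used
here; the two conventions differ and the reported numbers cannot satisfy
both at once, so the endpoint-consistent one was chosen and the parameter
is exposed (`NephronGeometry.nuclear_mass_fraction`). Activity is assumed
distributed over proximal tubules in proportion to their mass (43%
occupancy), under which the occupancy cancels from the dose ratio; the
field is retained for provenance. Glomerular dose is the photon self-dose
alone (electrons from tubule surfaces cannot reach glomeruli). The
striated-duct dose divides the salivary organ dose by a duct mass fraction
(default 1/20, reproducing the ~20× concentration factor).

## Synthetic biodistribution

Per tissue: `c(t) = (1 − e^{−t/τ}) · (A₁e^{−λ₁t} + A₂e^{−λ₂t})` in
decay-corrected %ID/g, with mean-unbiased multiplicative lognormal noise
per animal (CV 0.2 default, 5 animals/time) averaged per sacrifice time.
The closed-form physical TIAC of every generated dataset is recorded as
ground truth. Preset anchors: the shared slow clearance constant is fixed
by the kidney points 12.8 %ID/g at 2 weeks → 0.2 %ID/g at 12 weeks
(λ = ln 64 / 10 wk, effective half-life ≈ 1.67 wk); the tumor preset holds
a 2.0–2.5 : 1 tumor:kidney ratio from 48 h through 3 weeks and integrates
to ≈ 2.7 Gy/MBq (reported 2.6); salivary integrates to ≈ 13 mGy/MBq
(reported 12); the PSMA-negative tumor peaks below 1.4 %ID/g; the two
earliest kidney points are emitted as censored ("saturated") rows, as in
the source data. What the generator does *not* emulate: inter-animal
kinetic (as opposed to measurement) variability, strain differences,
tumor-volume dynamics, and dehalogenation kinetics — recovery tests
therefore validate the fit-and-integrate machinery, not biological realism.

One consequence is worth stating plainly: a mono-exponential tail through
the two kidney anchors alone integrates to ≥ 1.0 Gy/MBq, so the synthetic
kidney electron coefficient (~1.1–1.2 Gy/MBq) necessarily exceeds the
reported 0.71–0.99 Gy/MBq — the reported coefficient and the reported
concentration anchors are not simultaneously satisfiable under these
kinetics. Combined with the ~2× higher tubule nucleus fraction, the
end-to-end tumor-nucleus : tubule-nucleus dose ratio of the default
synthetic run lands near 14×, versus ~50× reported; each contributing
factor is within its own tolerance, but they compound in the same
direction. With the reported organ coefficients and deposition fractions
as inputs the package reproduces ~100 Gy vs ~2–4 Gy (ratio ~25–50×).

## Time-activity fitting

The tail is fit by ordinary least squares on log-concentration; the
breakpoint is the *earliest* time point whose suffix (≥ 3 points,
configurable to 2) reaches R² ≥ 0.9; earlier points become trapezoid
nodes. Series must be in physical-activity convention before fitting
(decay re-applied to decay-corrected data — otherwise the 59 d half-life
would be silently ignored and doses diverge). Head integration extrapolates
flat from the first quantified point to t = 0 (conservative when early
points are censored) and the reported `extrapolated_fraction` is the tail
share beyond the last datum. Zero/negative concentrations are excluded from
the log fit with a warning. Known bias: on genuinely multi-exponential
data the earliest admissible breakpoint can under- or over-shoot the true
integral by a few percent (−1 to −3% on the packaged presets); at zero
noise on a mono-exponential washout the recovery error is quadrature-only
(< 1%).

## Problem sizes and reproducibility

Default history counts — 10⁵ (cell), 2×10⁵ (tubule), 2×10⁵ per sphere ×
20 spheres (photon sweep) — put Monte Carlo standard errors well below the
geometric modelling freedom; the full default analysis runs in seconds.
Every stochastic routine takes an explicit seed; the pipeline derives all
stage seeds from one config seed, making full runs byte-identical. All
tunables (geometry, occupancy, duct fraction, R² threshold, noise CV,
history counts) live in the single analysis config with defaults at the
study values.

## Known limitations

* Water stands in for all tissues; no material heterogeneity.
* Straight-track electron transport: no explicit scattering, no
  energy-loss straggling, no δ-rays; sub-keV Augers deposit at the source.
* Photon transport ignores coherent scattering and electron-binding
  corrections to Compton scattering; fluorescence after photoabsorption in
  water is negligible and not modelled. The fitted power-law *intercept*
  (a ≈ 10 %/g vs reported 7.2) and the kidney photon AF (~6% vs ~4%) are
  sensitive to these transport details; the exponent is not.
* Photon dose is self-dose only; cross-organ photon dose is out of scope.
* Single cell/nucleus sizes, centred nuclei; no cell-to-cell cross-dose,
  no bystander effects, no RBE or BED weighting (channels are reported
  separately instead).
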