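# sheetnmr

Determining how β-strands are arranged inside self-assembling peptide
nanofibers — parallel or antiparallel, in or out of register — from
dipolar-recoupling solid-state NMR and FTIR data.

Self-assembling peptides such as Q11 (Ac-QQKFQFQFEQQ-Am) form amyloid-like
β-sheet nanofibers used as vaccine and tissue-engineering scaffolds. The
strand arrangement controls which residues sit next to each other and hence
how functional cargo is displayed, but it cannot be read off a fiber
micrograph. It can be inferred from through-space magnetic couplings:
the dipolar coupling between two spin-1/2 nuclei is

    d = μ0 γ₁ γ₂ ħ / (8 π² r³)   [Hz]

(≈ 47.9 Hz for ¹³C–¹⁵N at 4 Å, ≈ 60.8 Hz for ¹³C–¹³C at 5 Å — derived here
from CODATA gyromagnetic ratios), so selective isotope labeling plus
recoupling experiments that reintroduce this interaction under magic-angle
spinning measure inter-residue distances on the 3–6 Å scale.

`sheetnmr` implements the full quantitative chain for three such analyses,
with a synthetic-data generator standing in for the spectrometer:

* **Spin-dynamics simulation** (`sheetnmr.sequences`) — density-matrix
  propagation of REDOR (¹³C observe, ¹⁵N π-pulse dephasing, rotor
  synchronized), frequency-selective REDOR (ideal pair selection), and a
  constant-time finite-pulse ¹³C–¹³C recoupling sequence of the PITHIRDS
  type (π pulses of one-third rotor period, XY-8 supercycled, carbonyl CSA
  included), powder-averaged over deterministic orientation schemes.
  Analytic oracles (the Bessel-function REDOR universal curve
  `1 − (√2π/4) J₁/₄(√2λ) J₋₁/₄(√2λ)`, and the product-of-cosines
  commuting limit) validate the numerical engine.
* **Geometry** (`sheetnmr.geometry`) — idealized β-sheet lattices (5 Å
  strand spacing, 3.5 Å residue rise, 10 Å sheet spacing) and linear spin
  arrays; extraction of labeled-site spin systems; prediction of ¹³C–¹³C
  correlation (DARR) contacts within the 6 Å detectability range; PDB
  export.
* **Dephasing analysis** (`sheetnmr.analysis`) — Gaussian peak-intensity
  fitting with 95% intervals, natural-abundance background correction
  `E_true = (E_obs − f_na)/(1 − f_na)`, and exact constrained least-squares
  mixture fitting `min ‖y − Σ pᵢ bᵢ‖²` with `pᵢ ∈ [0,1]`, `Σpᵢ ≤ 1`
  (residual-bootstrap CIs). This is the estimator behind statements like
  "9% of labeled pairs are salt-bridged" or "22% antiparallel / 78%
  parallel".
* **FTIR β-index** (`sheetnmr.ftir`) — amide-I baseline correction,
  Savitzky–Golay smoothing, three-Gaussian decomposition, and the
  1693–1697 / 1624–1632 cm⁻¹ intensity ratio with the 0.1
  parallel/antiparallel classification threshold.
* **Synthetic data** (`sheetnmr.synthetic`) — canonical spin systems,
  noisy mixture dephasing curves, and synthetic amide-I spectra, all pure
  functions of their seed.

## Worked example

Simulate the two REDOR scenarios used to diagnose strand arrangement and
fit a noisy mixture curve:

```python
import numpy as np
from sheetnmr import (
    SequenceParams, SyntheticCurveSpec, fit_mixture, generate_noisy_curve,
    make_canonical_systems, powder_scheme, redor_times, simulate_redor,
)

systems = make_canonical_systems()
times = redor_times(mas_rate=10e3, t_max=61.44e-3, n_points=16)
params = SequenceParams("REDOR", 10e3, times)
powder = powder_scheme(377)

# eight-spin alternating 13C/15N array at 5 A: the "100% antiparallel" basis
basis = simulate_redor(systems["redor_4C4N_5A"], params, powder)
print(round(basis.values.max(), 3))          # 0.592

# synthetic sample: 22% antiparallel + 78% parallel (flat) + noise
spec = SyntheticCurveSpec((0.22,), ("anti",), noise_sigma=0.02,
                          time_grid=basis.times, seed=7)
noisy = generate_noisy_curve(spec, {"anti": basis})
res = fit_mixture(noisy, [basis], basis_names=["antiparallel_5A"])
print(round(res.fractions[0], 3), np.round(res.fraction_ci95[0], 3))
# 0.219 [0.204 0.231]
```

The eight-spin dephasing plateaus near 0.59 — far below the two-spin
limit of ~1.0 (`simulate_redor` on `pair_CN_5A` reaches 1.030 at 61.4 ms)
because passive ¹³C–¹³C couplings and multispin effects cap the
transferable dephasing; this is why quantifying arrangement fractions
against a two-spin curve alone would be misleading. The mixture fit
recovers the planted 22% antiparallel fraction with a bootstrap interval
that covers the truth.

The FTIR side:

```python
from sheetnmr import beta_index, generate_amide_spectrum
spec = generate_amide_spectrum(
    [(1625, 8, 1.0), (1650, 10, 0.35), (1695, 6, 0.082)],
    baseline_coeffs=(0.02, 1e-4), noise_sigma=0.002, seed=0)
res = beta_index(spec)
print(round(res.index, 3), res.classification)   # 0.082 parallel
```

A command-line interface mirrors these stages
(`sheetnmr simulate redor ...`, `sheetnmr fit mixture ...`,
`sheetnmr betaindex ...`, `sheetnmr build ...`, `sheetnmr fixtures ...`);
every result JSON carries a provenance block (input hashes, parameters,
seed, version).

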