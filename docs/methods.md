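# Methods

## The estimation problems

### Three-cube seFRET

A pixel (or bulk sample) contains `n_pairs` FRET-competent donor–acceptor
pairs with efficiency E, plus `n_d_free` free donors and `n_a_free` free
acceptors; f_D and f_A denote the interacting fractions of donors and
acceptors. Three acquisitions are made: donor excitation with donor
detection (I_DD), donor excitation with acceptor-channel detection (I_DA),
acceptor excitation with acceptor detection (I_AA). Each channel count is
Poisson around its mean.

Forward model (brightness convention: one donor excitation that decays
radiatively contributes one expected photon to I_DD; the calibration factors
η and ε absorb every remaining ratio of excitation intensity, quantum yield
and detection efficiency):

    mu_DD = g n_D (1 − f_D E) + B_DD
    s     = g n_D f_D E / η                      (sensitized emission)
    mu_AA = g (ε/η) n_A + B_AA
    mu_DA = s + DER·(mu_DD − B_DD) + AER·(mu_AA − B_AA) + B_DA

with g the exposure (expected detected photons per donor per acquisition),
n_D = n_pairs + n_d_free, n_A = n_pairs + n_a_free. The acceptor-channel
amplitude g(ε/η)n_A is the unique choice making both estimator identities
hold simultaneously: unmixing noise-free means returns dFRET = f_D·E and
aFRET = f_A·E exactly, for any crosstalk and calibration factors. The
abundance ratio r = n_A/n_D is the only extra degree of freedom.

Estimators (never clamped; non-positive denominators are flagged invalid so
per-pixel unmixing degrades gracefully):

    cFRET = I_DA − DER·I_DD − AER·I_AA
    dFRET = η cFRET / (I_DD + η cFRET)
    aFRET = ε cFRET / I_AA

Calibration: DER and AER are ratios of background-subtracted channel *sums*
of donor-only and acceptor-only references (sum-of-ratios would be biased at
low counts because the expectation of a Poisson ratio is not the ratio of
expectations); η and ε are solved in closed form from a fully interacting
reference of known efficiency.

### Precision bounds for seFRET

First-order error propagation over the three Poisson channels,

    Var(φ) = Σ_c (∂φ/∂I_c)² mu_c      (analytic partials),

evaluated at the means. The Fisher route parametrizes the means by
θ = (q, G, R) — q the estimand (f_D E or f_A E), G = g·n_D, R = n_A/n_D —
and computes Var(q̂) = (J⁻¹)₁₁ with J_ij = Σ_c mu_c⁻¹ (∂mu_c/∂θ_i)(∂mu_c/∂θ_j).
With three parameters behind three Poisson channels the plug-in estimator is
the exact maximum-likelihood estimator, so the two routes agree to numerical
precision at interior points; the package tests this at 200 random parameter
points. The equivalence holds only without background: the estimators do not
subtract a background, so with B > 0 the plug-in map is no longer the MLE of
the known-background model, and the error-propagation value (which describes
the estimator actually used, and is what the Monte-Carlo suite validates) is
the quantity reported.

Everything is reported as the normalized precision σ̃ = σ·√N_P with
N_P = mu_DD + mu_DA + mu_AA (signal plus background, all three channels; a
`np_channels="donor"` switch restricts the normalization to the two
donor-excitation acquisitions for sensitivity analysis). σ̃ is invariant
under exposure rescaling. The quadrature decomposition

    σ̃² = σ̃_E² + σ̃_SBT² + σ̃_B²

is defined by model ablation: σ̃_E is the bound with DER = AER = 0 and no
background (η, ε retained), σ̃_SBT² the additional term with crosstalk
restored, σ̃_B² the remainder with background restored. Tiny negative
intermediate differences (< 1e-12 relative) are floored at zero.

Background convention: a relative background β adds B_c = β·(signal mean of
channel c) to every channel, so the signal-to-background ratio is 1/β.
Background is treated as a known constant, not an estimated nuisance,
because the estimators above do not subtract it; the resulting systematic
error is exposed by `expected_bias` (plug-in evaluation at the means), which
the Monte-Carlo mean estimates reproduce within sampling error.

### TCSPC FLIM

Donor decay under pulsed excitation at period T = 1/rep_rate, recorded
modulo T into K bins. The wrapped-exponential bin mass for lifetime τ is

    p_k(τ) = (e^(−t_k/τ) − e^(−t_{k+1}/τ)) / (1 − e^(−T/τ)).

The signal is a two-component mixture: a fraction f of signal photons from
quenched donors with lifetime τ₀(1−E) and 1−f from unquenched donors with
the known lifetime τ₀, circularly convolved with a normalized IRF and
optionally mixed with a uniform uncorrelated background fraction b. With the
total count fixed, the histogram is multinomial and

    J_ij = N Σ_k p_k⁻¹ (∂p_k/∂θ_i)(∂p_k/∂θ_j),    θ = (E, f[, b]),

gives σ̃ = √(Var(Ê)·N_signal), normalized to the donor *signal* photons
(background excluded) and independent of N by construction. Defaults follow
a high-end system: 80 MHz repetition, 256 bins, τ₀ = 3 ns, Dirac IRF; a
wrapped-Gaussian IRF of configurable FWHM (38 ps reproduces a realistic
hybrid-detector response) or an arbitrary two-column-CSV IRF can be
substituted.

f in the decay model is a *photon* fraction. Case studies quoting the
fraction of interacting donor *molecules* are converted with

    f_photon = f_mol (1−E) / ((1−f_mol) + f_mol (1−E)),

since each interacting donor emits (1−E) times the photons of a free donor;
the literal photon-fraction reading remains available for sensitivity
analysis.

## Parameters that matter

| parameter | meaning | default | why |
|---|---|---|---|
| DER, AER | spectral bleed-through, direct excitation | 0 | ideal system; canned confocal (0.42/0.60) and wide-field (1.07/0.29) instances provided |
| η, ε | dFRET/aFRET normalization factors | 1 | ideal system; confocal 0.52/6.3, wide-field 0.015/42 |
| β | relative background per channel | 0 | background-free reference case; sweeps use 0–0.6 |
| g (exposure) | detected photons per donor | 1 | σ̃ is exposure-invariant; Monte-Carlo runs use g = 20–100 to sit in the asymptotic regime |
| τ₀ | unquenched donor lifetime | 3 ns | typical fluorescent-protein donor |
| rep_rate, n_bins | TCSPC timing | 80 MHz, 256 | high-end TCSPC hardware |
| E cap | maximum efficiency | 0.99 | τ₂ → 0 is numerically degenerate under binning |
| n_rep | Monte-Carlo replicates | 10⁴ | SE of a SD ≈ 0.7%, resolving 2-significant-figure bounds |

## Numerical choices

- **TCSPC derivatives** are central finite differences (step 1e-5; shrunk
  near a domain boundary, one-sided exactly at one). The circular IRF
  convolution makes closed-form partials error-prone; a step-halving test
  guards accuracy (1e-4 relative), and the single-unknown variant reproduces
  the closed-form single-exponential limit σ̃ → 1−E to <2% for fine bins and
  T ≥ 10 τ₂.
- **Singular Fisher matrices** (condition number > 1e12–1e14) raise a
  diagnostic error rather than being pseudo-inverted: at E = 0 the two decay
  components coincide and f is unidentifiable; at f = 0 there are no
  quenched photons and E is unidentifiable. Sweep tables report such grid
  points as NaN.
- **MLE decay fits** maximize the multinomial log-likelihood with L-BFGS-B
  from four deterministic starts spread over the (f, E) square; fits attain
  the CRLB (sample SD of Ê within 15% of the bound at 500 × 10⁵-photon
  replicates).
- **Invalid unmixes** in Monte-Carlo runs (non-positive denominators at low
  counts) are excluded and counted; more than 50% exclusions aborts with a
  degenerate-regime error, since the normalized-precision description
  presupposes the asymptotic regime.
- **photon_budget** rounds half-up to whole photons; the unrounded ratio is
  available (`rounded=False`).
- **Efficiency grids** default to the power series E_i = 0.99·(i/127)²,
  denser near E = 0 where the bounds change fastest.
- All simulation randomness flows from one explicit integer seed through
  `numpy.random.Generator`; runs are bit-reproducible.

## What the synthetic data does and does not emulate

The generators produce exactly the stochastic model the bounds assume:
independent Poisson channel counts (or fixed-total multinomial decay
histograms) around the forward-model means, plus piecewise-constant test
images with donor-only/acceptor-only/mixed regions. They do not emulate
camera read noise or EM gain, detector dead-time or pile-up, photobleaching,
spatial correlations, chromatic aberrations, or realistic cell morphology.
Passing the Monte-Carlo agreement tests therefore shows the analytic bounds
correctly describe Poisson-limited acquisition — the stated scope — not that
real detectors reach them; statistical errors in the DER/AER/η/ε reference
measurements themselves are likewise out of scope.

## Design notes and known limitations

- At a fixed repetition period the TCSPC bound is *not* monotone in τ₀: a
  longer lifetime resolves high efficiencies better than a short one (the
  quenched lifetime stays above the bin width), but once τ₀ approaches the
  12.5 ns period the wrapped decay flattens toward uniform and information
  collapses (at E = 0.5, f = 0.5: σ̃ = 2.3/2.6/10 for τ₀ = 1/3/10 ns). The
  common rule of thumb "longer τ₀ is better" holds only while τ₀ ≪ T.
- The two-parameter TCSPC bound diverges as E → 0 (the components become
  indistinguishable, so the unknown fraction destroys identifiability) and
  is therefore very large for small E at low f. Robustness to an estimated
  uniform background (penalty factor < 2 for 100 background photons on
  ~1500 signal photons) holds for E ≥ 0.5 but degrades in that low-E
  near-degenerate corner.
- With 256 bins of 48.8 ps, a 38 ps-FWHM Gaussian IRF is narrower than one
  bin; it matters (>5% on σ̃) only above E ≈ 0.985, where the quenched
  lifetime falls to tens of picoseconds.
- dFRET at exactly E = 0 (ideal system) returns σ̃ = 0: with no crosstalk,
  an empty sensitized channel identifies E = 0 with certainty; likewise the
  bound collapses approaching E = 1 where the donor channel empties. These
  are genuine limits of the model, not numerical artifacts.
- Raw σ̃ of dFRET and aFRET are directly comparable only when they estimate
  the same quantity (f_D = f_A); across unequal fractions the meaningful
  pointwise statement — tested here — is that the donor-normalized
  estimator's SNR, (f_D E)/σ, is never worse than the acceptor-normalized
  one's.
- TCSPC pile-up and dead-time distortions, time-gated/frequency-domain FLIM
  and >3-channel spectral unmixing are out of scope.
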