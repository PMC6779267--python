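# Methods

## The model

Each cortical region `j` is a Stuart-Landau (Hopf normal form) oscillator
with complex state `z_j = r e^{iθ}` and an *adaptive* angular frequency
`ω_j`, coupled diffusively through a structural connectome `C`:

    dz_j/dt = (a_j + i ω_j − |z_j|²) z_j + G Σ_i C_ij (z_i − z_j) + β η_j
    dω_j/dt = ω0_j − λ ω_j + m ψ_j,      ψ_j = Σ_i C_ij θ_i

`a_j` is the bifurcation parameter: for `a > 0` the uncoupled noise-free
region has a stable limit cycle of radius `√a`; for `a < 0` a stable fixed
point with noise-driven fluctuations. `G` scales coupling; `β η_j` is
additive complex white noise (independent real/imaginary Wiener
increments, default `β = 0.02`); `ω0_j` is the intrinsic frequency drive,
`λ` ("frequency lethargy", 1/s) damps the free-running frequency toward
`ω0_j/λ`, and `m` modulates it by the net phase `ψ_j` of the structural
neighbourhood. Inside `ψ_j` the phase `θ_i` is deliberately the
**two-quadrant** arctangent `atan(Im z/Re z) ∈ [−π/2, π/2]` (with
`sign(Im z)·π/2` on the imaginary axis and 0 at the origin); signal-level
phase measures use the conventional four-quadrant phase of the analytic
signal instead. With `m = 0` the system reduces to classic coupled
Stuart-Landau oscillators whose relaxed frequencies are `ω0/λ` — the
comparison model throughout.

The observable is `Re z` ("BOLD-like"); the imaginary part is a hidden
state.

## Integration

Euler–Maruyama with per-step noise SD `β√dt` in each component. Defaults:
`dt = 0.01 s`, `burn_in = 60 s`, output every `tr = 0.72 s`, 1190 output
samples (a standard resting-state run length). Unit tests and examples use
`dt = 0.04 s` (it divides `tr` exactly, so samples land on the step grid)
with shorter runs. Initial conditions: `z` uniform on the complex disk of
radius `max(√max(a,0), 0.1)`, `ω(0) = ω0/λ`.

Numerical caveats, verified in the test suite:

* The scheme is first order; halving `dt` roughly halves noise-free
  trajectory error.
* Under rotation, Euler inflates the limit-cycle radius by `O(dt·ω²)`
  (the per-step map multiplies `|z|` by `|1 + dt(a − r² + iω)|`). Radial
  fixed-point checks therefore run with `ω = 0`, where the amplitude
  equation decouples and the fixed point `r* = √a` is exact.
* An accelerated numba kernel mirrors the pure-numpy reference loop on the
  identical RNG stream; the two agree to machine precision over short
  horizons and diverge only by chaotic amplification of last-bit
  differences over long noisy runs. Both are deterministic per seed.

A stated "limit cycle of radius a" reading of the amplitude equation is
inconsistent with the equation itself; the implementation follows the
equation (`r* = √a`).

## Connectome construction

Subject connectomes are synthetic stand-ins for tractography: a modular
group template (within-system edge odds 4× between-system, log-normal
weights), each subject zeroing an independent `dropout` fraction of
template edges. The group matrix keeps an edge when ≥ 60% of subjects
express it (a consistency rule), averaging **including** the zeros of
non-expressing subjects — this preserves the streamline-density scale and
matches common practice; the alternative (mean over expressing subjects
only) is a one-line change. Nonzero weights are then rank-mapped onto
Gaussian quantiles `Φ⁻¹(rank/(M+1))·σ + μ` with `μ = 0.5, σ = 0.15`;
the plotting position `rank/(M+1)` keeps extremes finite, and ties break
by stable edge-index order for determinism.

Path-based centralities use edge length `1/weight` (standard for
streamline-density graphs). Closeness is the inverse mean distance over
the reachable set; unreachable pairs are excluded from betweenness. The
hub score is the mean of unity-normalized (`(x−min)/(max−min)`, all-zero
when degenerate) strength, betweenness and closeness, and is invariant
under global weight rescaling.

## Observables

* Static FC: Pearson correlations; group FC by Fisher-z averaging
  (|r| clipped at 1−1e−7).
* Modularity: Newman's `Q = (1/v) Σ_ij (w_ij − s_i s_j/v) δ_ij` over all
  ordered pairs including `i = j` with `w_ii := 0`; negative FC weights
  clipped to 0 (the measure assumes positive weights). This convention
  recovers `Q = 0.5` for two disconnected dyads.
* Phases: analytic signal of the demeaned columns; the first and last 5%
  of samples are trimmed against Hilbert edge effects (configurable).
  A flag allows using model phases `arg z` directly.
* Instantaneous phase coherence: `1 − |sin Δθ|`; dynamic FC is the
  distribution of cosine similarities between half-vectorized coherence
  matrices over all (or a seeded subsample of, default cap 250 000)
  unordered time-point pairs; distributions compared by the two-sample
  Kolmogorov-Smirnov statistic.
* Order parameter `r(t) = |mean_j e^{iθ_j}|`; synchrony = time mean,
  metastability = time SD.
* Intrinsic frequencies: per subject and node, the in-band (0.02–0.12 Hz)
  Welch spectral peak (`nperseg = min(256, T/2)`, 50% overlap); median
  across subjects, returned as `2πf` rad/s.

## Fitting

The composite score of a parameter cell against reference summaries
averages five unity-normalized distances: `(1 − r_FC)/2`, `|Q − Q_ref|`,
the dFC KS distance, and the absolute synchrony and metastability gaps.
Normalization is over the full grid (a distance that is constant across
the grid contributes zero). The grid is evaluated lexicographically with a
common simulation seed per cell; `n_rep > 1` averages each cell's raw
distances over several noise realizations whose seeds are shared across
cells (common random numbers), which is the recommended setting whenever
the reference was generated with independent noise. Matching the reference
modularity (rather than maximizing it) is the default, conservative
reading; both are available.

Model comparison uses AIC over per-subject composite scores with a
Gaussian likelihood (MLE mean/variance): `k = 4` for the adaptive model
(`a, G, λ, m`) versus `k = 2` for the classic `m = 0` model (`a, G`). Both
AICs and their difference are reported without further adjudication.

### Identifiability at desk scale

In the fitted regime the coupling input `G·Σ C_ij` exceeds `a`, so regions
sit below the effective bifurcation and signals are noise-driven; the FC
fingerprint of a single run is then weakly reproducible (run-to-run FC
correlation ~0.1 at 600 samples). Consequences, measured in the test
suite: with `β = 0` and a shared seed, grid-search recovery of a known
working point is exact; with `β = 0.02` and an independently generated
multi-subject reference, single-realization evaluation cannot localize
the optimum, while 6-realization averaging over a 16-subject reference
recovers it to within one grid step in ≥ 8/10 seeds (32 nodes, 600
samples, 5×5 grid). Node count and coupling trade off: the tests scale
`G` with `1/Σ C_ij` to hold the regime fixed when downscaling.

## Lesion suite

A lesion sets a region's `a` to −2 (deep noise-driven regime). All lesion
simulations reuse the baseline's noise seed by default so differences are
attributable to the lesion, not the noise path (a flag gives independent
seeds).

* **Robustness**: perturb `⌊fN⌋` regions simultaneously (random draws,
  averaged over `n_rep`, default 100; or descending structural hub score),
  binarize the simulated FC at an absolute threshold, and record the giant
  component relative to baseline (capped at 1; a lesioned run can
  occasionally reconnect nodes the baseline giant missed). Meaningful
  attack-strategy separation requires coupling strong enough that
  periphery FC is hub-mediated and runs long enough that the FC noise
  floor sits below threshold; the packaged experiment uses a
  core-periphery connectome, `G = 0.06`, 800 samples and threshold 0.15.
* **Threshold selection**: sweep 100 absolute thresholds, score simulated
  against reference FC as a binary classifier; report accuracy, precision
  (undefined points excluded), a least-squares cubic fit to precision, the
  curvature knee `|y″|/(1+y′²)^{3/2}` (boundary-flagged when degenerate)
  and the accuracy/precision crossing by linear interpolation, ties toward
  the smaller threshold.
* **Vulnerability**: relative change of signed FC nodal strength (row sums
  excluding the diagonal, negatives retained; positive-clip behind a
  flag) per lesion; positive and negative changes averaged separately into
  hyper-/hypo-connectivity maps. Link vulnerability does the same for
  mean inter-system FC.
* **Hazard**: per set (baseline + N lesions), 13 static features with six
  systems — global efficiency and per-system local efficiency, each
  normalized by degree-preserving double-edge-swap nulls (20 realizations,
  10·|E| swaps; complete graphs return 1 exactly), plus per-system
  segregation `(within − between)/within` — each feature unity-normalized
  across the N+1 sets (undefined entries imputed with the across-set
  median). The static distance is each lesion's Euclidean distance from
  baseline; the phase distance combines unity-normalized synchrony and
  metastability gaps with the dFC KS distance entering directly as the
  third coordinate. Each distance is unity-normalized across the N
  lesions (baseline excluded from this final basin) and summed into the
  hazard score ∈ [0, 2]. Hazard is correlated with clustering, degree,
  strength and local efficiency; two-sided p-values are
  Benjamini-Hochberg-corrected across the four tests.
* "Largest strongly connected component" of a symmetric FC graph is read
  as the plain connected component; direction is meaningless here.

## Synthetic studies

`generate_reference_study` emulates a resting-state study: subject
connectomes as above; per-subject signals from the model itself on the
group connectome at the documented ground-truth working point
(`a = 0.038, G = 0.01, λ = 0.4, m = 0.14` — the fitted regime), with
subject-specific seeds and additive white observation noise. Per-node peak
frequencies are drawn uniformly in the 0.02–0.12 Hz band; `ω0` is stored
as `λ·2πf` so the relaxed free-running frequency equals the drawn peak
(set `scale_omega0_by_lambda=False` to store `2πf` verbatim). The
generator does **not** emulate hemodynamic convolution, scanner drift,
motion, or physiological noise spectra — passing tests demonstrate the
pipeline's internal consistency, not performance on real BOLD data. The
phase-driven frequency modulation shifts realized spectral peaks by up to
~0.01 Hz from the drawn truth; at the default run length this stays
within one Welch bin.

## Problem sizes

Examples and tests run desk-scale configurations chosen once: 12–68
nodes, 100–800 output samples, 50–100 random-attack repetitions, 20 null
realizations, 3–6 fit repetitions. Full-scale settings (1190 samples,
2000 repetitions, the 71×15×5×11 fine grid) are plain configuration
values.

## Known limitations

* First-order integration; no higher-order SDE scheme.
* No hemodynamic forward model; `Re z` is compared to band-limited BOLD
  directly.
* No delays in coupling.
* Welch-bin granularity (~0.009 Hz at default lengths) limits frequency
  estimation; parameter identifiability at single-run, single-subject
  scale is intrinsically weak in the noise-driven regime (see above).
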