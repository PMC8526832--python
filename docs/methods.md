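# Methods

## Model

`bgpseq` implements a family of probabilistic sequence classifiers for
longitudinal health-record data.  A patient's history is a sequence of
encounter tokens (diagnosis/medication surrogate codes), organized into
visits.  Each encounter is embedded as the sum of four learned tables — code,
integer-year age, visit-parity segment, and visit-rank position — and encoded
by a stack of post-norm transformer layers with attention masking over
padding.  The representation of the first (classification) position is pooled
through an affine map with tanh transfer, so pooled features live in
(-1, 1)^d.  A classifier head maps pooled features to the probability of a
binary outcome.

Six variants share this skeleton and differ in (a) which parameter groups
carry mean-field Gaussian posteriors instead of point weights and (b) the
classifier:

| variant   | stochastic groups        | classifier                  |
|-----------|--------------------------|-----------------------------|
| DBGP      | embeddings               | KISS-GP (grid interpolation)|
| BE        | embeddings               | linear                      |
| BO        | classifier               | linear (mean-field)         |
| BE+BO     | embeddings + classifier  | linear (mean-field)         |
| Sparse-GP | none                     | sparse variational GP       |
| KISS-GP   | none                     | KISS-GP                     |

The hybrid (DBGP) propagates weight uncertainty from the embedding layer
through the deterministic encoder into a Gaussian-process classifier, so the
predictive distribution reflects both input-representation uncertainty and
latent-function uncertainty.  With the embedding variances clamped to zero it
reduces exactly to deterministic kernel learning with a KISS-GP head; this
reduction is enforced by a test.

## Variational machinery

Every stochastic weight has an independent Gaussian posterior
q(w) = N(mu, softplus(rho)^2) against a N(0, 0.374^2) prior; sd is
parameterized through softplus so positivity is unconditional, and the
initial sd is 0.05 (small relative to the prior, so warm-started means are
not immediately swamped by sampling noise).  Sampling is reparameterized
(mu + sd * eps), the KL to the prior is closed-form, and minibatch i of M
receives the geometric KL weight 2^(M-i)/(2^M - 1), which sums to one over an
epoch.

The GP heads use a whitened variational Gaussian q(v) = N(m, CC^T) with
N(0, I) prior over inducing values; C is lower-triangular with softplus
diagonal.  The sparse head carries 40 free inducing points (default) in the
pooled space.  The KISS head imposes the grid constraint: because a
tensor-product grid is infeasible in d = 8-24 dimensions, it uses an additive
kernel — one 1-D RBF kernel on its own grid (default 64 points over
[-1.1, 1.1], which always covers the tanh-bounded features) per pooled
dimension, with per-dimension latent GPs summed.  Cross-covariances use local
linear interpolation on the two adjacent grid points, so the whitened
projector is A = W L with two non-zeros per row of W.  Both heads carry a
trainable constant mean (see Optimization).  Out-of-grid queries are clamped
to the boundary with a warning.  All Cholesky factorizations add 1e-6 jitter
(the regression-mode free-energy oracle uses adaptive jitter from 1e-12 so
that inducing-points-equal-inputs reproduces the exact marginal likelihood to
1e-6).  Expectations of the Bernoulli log-likelihood and the
logistic-Gaussian integral use Gauss-Hermite quadrature of order 20
throughout; the per-point latent variance is floored at 1e-10.

## Training objective

One weight draw per minibatch (Bayes by Backprop).  The per-step loss is

    (N/B) * data-NLL + GP-KL / M + pi_i * weight-KL,   divided by N,

where the data term is the Bernoulli negative log-likelihood (linear heads)
or the Gauss-Hermite expected Bernoulli term of the classification ELBO (GP
heads), GP-KL is the whitened Gaussian KL (counted once per epoch sweep),
and pi_i is the geometric minibatch weight.  How the two KL terms are jointly
scaled is a genuine design choice; this scheme keeps each term's epoch total
at exactly one full KL.  Adam with the reference defaults (lr 3e-5, weight
decay 0.01, batch 64) is the configured default.  Weight decay is decoupled —
applied to the weights directly, never added to the gradient that feeds
Adam's adaptive normalizer, which would otherwise let the decay direction
crush any parameter whose data gradient is small (embedding tables, in
practice) — and is not applied to rho parameters or GP hyperparameters.
Training aborts with diagnostics if the loss diverges past ten times its
initial value, and is bitwise reproducible under a fixed seed.

## Optimization at desk scale

The reference configuration (hidden 150, 4 layers, ~10^6 patients, masked-LM
pretraining before fine-tuning) is far beyond CPU test budgets.  The package
therefore ships a desk-scale configuration (vocab 120, hidden 32, 2 layers,
2 heads, max length 64) and a documented optimization recipe whose elements
are standard practice rather than new modelling (the warm stage uses batch
256 at learning rate 3e-3; the variational fine-tune keeps the reference
3e-5):

* **Base-rate output initialization.**  The classifier starts at the cohort
  log-odds (a constant GP mean function, or the linear bias).  With a 10%
  positive rate and small learning rates, hundreds of steps are otherwise
  spent fitting the intercept before any ranking signal is learned.
* **Warm-started variational training.**  Stochastic-embedding variants first
  train their deterministic special case (embedding variances clamped, no
  weight-KL), then unclamp so the variational means start from trained
  weights, and fine-tune the full objective at the reference learning rate
  3e-5.  This mirrors the original procedure of centering variational
  posteriors at pretrained point weights.  It is also a practical necessity:
  at n = 2000 the weight-KL is ~7.5 nats per sample against a ~0.33-nat data
  term, so cold-start variational training collapses the posterior to the
  prior and the model to a constant predictor.  The warm start gives the data
  term a head start; the brief low-rate fine-tune adapts the variances
  without destroying the means.  Consequently the posterior variances remain
  close to their 0.05 initialization — the predictive uncertainty measured at
  desk scale reflects an under-trained posterior, which is stated plainly as
  a limitation below.

## Synthetic cohorts

The generator emulates the sequential structure of primary-care records:
3-8 visits per patient, 2-5 codes per visit drawn uniformly from the code
vocabulary, a leading CLS token, SEP-terminated visits, ages starting uniform
in [40, 70] and advancing 0-2 years per visit, segment ids alternating 0/1
per visit, and position ids equal to the visit rank.  The outcome follows a
planted logistic risk process: presence of designated risk tokens contributes
known log-odds effects, Gaussian noise (sd 0.5) on the log-odds scale makes
the Bayes-optimal classifier imperfect (both reducible and irreducible error
exist), and the intercept is bisected so the realized positive fraction hits
the target (default 10%, matching the 8-16% imbalance of the real tasks).
The default risk process plants two strong risk factors (+3.5, +2.5), one
moderate (+1.5), and one protective (-1.0) code, chosen so that Bayes-optimal
probabilities span the unit interval the way a real risk model's predictions
do — with only weak effects, no classifier can ever cross the 0.5 decision
threshold and the predicted-positive cells of the evaluation suite would be
structurally empty.  The noiseless per-patient log-odds are returned as a
ground truth for oracle checks (their ranking achieves AUROC ~0.88-0.92
against the drawn labels at n = 2000).

What the generator does **not** model: real ICD-10/BNF code statistics,
calendar time and negative-sample time-point selection, code co-occurrence
structure, visit-frequency/outcome correlation, or cohort-selection funnels.
Passing tests on these cohorts therefore demonstrate the machinery
(inference, uncertainty propagation, evaluation), not clinical validity.

## Monte-Carlo inference modes

`mc_predict` draws `S = 30` weight samples per patient (a 30-versus-60
robustness check is part of the acceptance run).  For GP heads two modes
exist.  The default marginalizes the latent function on every draw
(`E[logistic(f)]` under the latent Gaussian), so purely deterministic
variants produce literally identical samples and a predictive std of exactly
zero.  With `sample_latent=True` each draw additionally samples the
inducing-value posterior and the residual conditional — treating the GP's
variational weights like any other stochastic weight, so that "each set of
weights is an independent model".  The uncertainty-pattern analyses
(calibration bands, TP/FP std splits) use this mode for GP-head variants:
without it a deterministic-encoder GP model would show zero band width and
the GP contribution to the hybrid's epistemic spread would be invisible.

## Evaluation suite

* **Ranking**: AUROC and average precision on mean predictive probabilities,
  with 95% percentile CIs from 50 patient-level bootstrap resamples.
* **Rejection curves**: accuracy and AUROC over patients whose confidence
  (max of p and 1-p) exceeds each threshold in a [0.5, 0.95] grid; ties at
  0.5 are predicted negative; empty rows are flagged, not errors.
* **Calibration with epistemic bands**: each MC draw is one model; equal-width
  bins on [0, 1]; per-bin mean and 2.5/97.5-percentile envelope across draws.
* **DIV**: per prediction sign, Gaussians are fitted (sample mean, n-1 sd) to
  the predictive stds of incorrect (F) and correct (T) predictions and
  KL(F || T) is reported in nats — the divergence direction follows the
  defining equation, not the surrounding prose, and a per-sign computation is
  used (a pooled variant is available).  Degenerate cells (< 2 members or
  zero variance) yield an explicit reason code instead of a number.
* **Embedding entropy**: per code token, the summed Gaussian differential
  entropy across embedding dimensions, in nats; tables are sorted ascending
  (most certain first) and exclude special tokens.

## Numerical choices

Float64 throughout; Gauss-Hermite order 20; Cholesky jitter 1e-6 (adaptive
from 1e-12 in the regression oracle); latent variance floor 1e-10; logistic
probabilities clipped to [1e-12, 1-1e-12]; attention masking by additive
-1e9 before softmax; sample standard deviations use n-1; natural logarithms
everywhere.  Identical MC samples short-circuit to a predictive std of
exactly zero so deterministic variants report 0, not rounding noise.

## Known limitations

* In the synthetic risk process, false positives among predicted positives
  are label-noise flips of genuinely high-risk profiles, so the model's
  epistemic state about them is identical to that of true positives by
  construction.  The mean-std separation between FP and TP is then a weak
  composition effect and is not reliably positive for the hybrid variant
  (its per-sign DIV remains strictly positive, and the FN-versus-TN
  separation is large and robust).  This is a property of the generator, not
  of the method; real-data errors concentrate in sparse feature regions.
* Desk-scale posteriors are under-trained (variances near initialization);
  directional uncertainty patterns (FP vs TP spread, calibration-band
  asymmetry) are meaningful, their magnitudes are not.
* The additive-kernel KISS head is an interpretable, tractable stand-in for a
  tensor-product grid; it cannot represent interactions between pooled
  dimensions inside the kernel.
* Masked-LM pretraining is exposed only as a checkpoint-loading hook
  (`load_pretrained_means`) and is not exercised at scale.
* The sequence encoder indexes positions by visit rank; whether encounters or
  visits should be indexed is ambiguous in the source architecture and is
  fixed here as visits.
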