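"""Seeded synthetic longitudinal patient cohorts with a known risk process.

Real primary-care datasets of the kind this package targets are
license-restricted, so every downstream module is exercised on synthetic
cohorts that reproduce the sequential structure of such records: multi-visit
sequences of diagnosis/medication surrogate codes, a leading classification
token, visit separators, per-encounter ages that never decrease, alternating
visit-parity segment ids, and visit-rank position ids.

Labels come from a planted logistic risk process: a small set of "risk tokens"
carries known log-odds effects, Gaussian noise on the log-odds scale makes the
Bayes-optimal classifier imperfect (so uncertainty metrics have nontrivial
targets), and the intercept is tuned by bisection so the realized positive
fraction matches the requested class imbalance.  The noiseless per-patient
log-odds are returned as a ground-truth table for oracle checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

SPECIAL_TOKENS = ("PAD", "CLS", "SEP", "MASK", "UNK")
PAD, CLS, SEP, MASK, UNK = range(5)


class CohortConfigError(ValueError):
    """Raised when a cohort specification is internally inconsistent."""


class CohortParseError(ValueError):
    """Raised when a cohort file line cannot be parsed; names the line."""


@dataclass(frozen=True)
class Vocabulary:
    """Ordered token list with a bijective token <-> id mapping.

    Ids are contiguous from 0; the five special tokens occupy the first five
    slots exactly once.
    """

    tokens: tuple[str, ...]

    def __post_init__(self):
        for i, special in enumerate(SPECIAL_TOKENS):
            if self.tokens[i] != special:
                raise CohortConfigError(
                    f"special token {special!r} must occupy id {i}"
                )
        if len(set(self.tokens)) != len(self.tokens):
            raise CohortConfigError("vocabulary tokens must be unique")

    @classmethod
    def build(cls, n_codes: int) -> "Vocabulary":
        codes = tuple(f"C{i:04d}" for i in range(n_codes))
        return cls(tokens=SPECIAL_TOKENS + codes)

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def code_ids(self) -> np.ndarray:
        return np.arange(len(SPECIAL_TOKENS), len(self.tokens))

    def index(self, token: str) -> int:
        return self.tokens.index(token)

    def write(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.tokens) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "Vocabulary":
        return cls(tuple(Path(path).read_text().splitlines()))


@dataclass
class PatientRecord:
    """One patient's encounter sequence plus the binary outcome label.

    All four index sequences are aligned: ``codes[t]`` happened at integer age
    ``ages[t]``, inside the visit with parity ``segments[t]`` and visit rank
    ``positions[t]``.  The first token is always CLS; each visit's codes are
    followed by a SEP token carrying the same visit indices.
    """

    codes: list[int]
    ages: list[int]
    segments: list[int]
    positions: list[int]
    label: int

    def __len__(self) -> int:
        return len(self.codes)

    def validate(self, max_len: int | None = None) -> None:
        n = len(self.codes)
        if not (len(self.ages) == len(self.segments) == len(self.positions) == n):
            raise CohortConfigError("record sequences have unequal lengths")
        if max_len is not None and n > max_len:
            raise CohortConfigError(f"record length {n} exceeds maximum {max_len}")
        if n == 0 or self.codes[0] != CLS:
            raise CohortConfigError("record must start with CLS")
        if any(a2 < a1 for a1, a2 in zip(self.ages, self.ages[1:])):
            raise CohortConfigError("ages must be non-decreasing")
        # positions increment only when a SEP has just been passed
        for t in range(1, n):
            step = self.positions[t] - self.positions[t - 1]
            if step not in (0, 1) or (step == 1 and self.codes[t - 1] != SEP):
                raise CohortConfigError(
                    "positions must be non-decreasing and increment only at SEP"
                )


@dataclass(frozen=True)
class CohortSpec:
    """Generative settings for a synthetic cohort."""

    n_patients: int = 2000
    positive_rate: float = 0.10
    vocab_size: int = 120          # total including the 5 special tokens
    # a planted risk stratum: strong and moderate risk factors plus one
    # protective code, so Bayes-optimal probabilities span the unit interval
    # the way real risk models' predictions do
    risk_tokens: dict[int, float] = field(
        default_factory=lambda: {5: 3.5, 6: 2.5, 7: 1.5, 8: -1.0}
    )
    n_visits_range: tuple[int, int] = (3, 8)
    codes_per_visit_range: tuple[int, int] = (2, 5)
    baseline_log_odds: float | None = None   # None -> tuned by bisection
    nuisance_noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.positive_rate < 1.0:
            raise CohortConfigError("positive_rate must lie in (0, 1)")
        if self.n_visits_range[0] > self.n_visits_range[1] or self.n_visits_range[0] < 1:
            raise CohortConfigError("n_visits_range must be a non-empty positive interval")
        lo, hi = self.codes_per_visit_range
        if lo > hi or lo < 1:
            raise CohortConfigError("codes_per_visit_range must be a non-empty positive interval")
        n_codes = self.vocab_size - len(SPECIAL_TOKENS)
        if n_codes < 1:
            raise CohortConfigError("vocab_size must exceed the special-token count")
        bad = [t for t in self.risk_tokens if not len(SPECIAL_TOKENS) <= t < self.vocab_size]
        if bad:
            raise CohortConfigError(
                f"risk tokens {bad} outside the code-token id range "
                f"[{len(SPECIAL_TOKENS)}, {self.vocab_size})"
            )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _tune_baseline(scores: np.ndarray, target: float) -> float:
    """Bisection on b so that mean sigmoid(b + scores) == target."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _sigmoid(mid + scores).mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[PatientRecord], np.ndarray, Vocabulary]:
    """Draw a cohort; returns (records, true noiseless log-odds, vocabulary).

    Each patient receives a random number of visits; each visit a random set
    of code tokens drawn uniformly from the code vocabulary.  The label is
    Bernoulli(sigmoid(b + sum of risk-token effects + Gaussian noise)); the
    returned truth table holds the noiseless log-odds b + sum of effects.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    vocab = Vocabulary.build(spec.vocab_size - len(SPECIAL_TOKENS))
    code_ids = vocab.code_ids

    records: list[PatientRecord] = []
    effect_sums = np.zeros(spec.n_patients)
    for i in range(spec.n_patients):
        n_visits = int(rng.integers(spec.n_visits_range[0], spec.n_visits_range[1] + 1))
        age = int(rng.integers(40, 71))
        codes = [CLS]
        ages = [age]
        segments = [0]
        positions = [0]
        present: set[int] = set()
        for v in range(n_visits):
            n_codes = int(
                rng.integers(spec.codes_per_visit_range[0], spec.codes_per_visit_range[1] + 1)
            )
            visit_codes = rng.choice(code_ids, size=n_codes, replace=False)
            for c in visit_codes:
                codes.append(int(c))
                ages.append(age)
                segments.append(v % 2)
                positions.append(v)
                present.add(int(c))
            codes.append(SEP)
            ages.append(age)
            segments.append(v % 2)
            positions.append(v)
            age += int(rng.integers(0, 3))
        effect_sums[i] = sum(spec.risk_tokens.get(t, 0.0) for t in present)
        records.append(
            PatientRecord(codes=codes, ages=ages, segments=segments,
                          positions=positions, label=0)
        )

    noise = rng.normal(0.0, spec.nuisance_noise_sd, size=spec.n_patients)
    if spec.baseline_log_odds is None:
        baseline = _tune_baseline(effect_sums + noise, spec.positive_rate)
    else:
        baseline = spec.baseline_log_odds
    probs = _sigmoid(baseline + effect_sums + noise)
    labels = (rng.random(spec.n_patients) < probs).astype(int)
    for rec, y in zip(records, labels):
        rec.label = int(y)
    true_log_odds = baseline + effect_sums
    return records, true_log_odds, vocab


# --------------------------------------------------------------------- file IO

def write_cohort(
    records: list[PatientRecord],
    path: str | Path,
    spec: CohortSpec | None = None,
    true_log_odds: np.ndarray | None = None,
) -> None:
    """Write a cohort as JSON-lines: one header line, then one patient per line."""
    path = Path(path)
    header: dict = {"format": "bgpseq-cohort-v1", "n_patients": len(records)}
    if spec is not None:
        sp = asdict(spec)
        sp["risk_tokens"] = {str(k): v for k, v in sp["risk_tokens"].items()}
        header["spec"] = sp
        header["seed"] = spec.seed
    with path.open("w") as fh:
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for i, rec in enumerate(records):
            row = {
                "codes": rec.codes,
                "ages": rec.ages,
                "segments": rec.segments,
                "positions": rec.positions,
                "label": rec.label,
            }
            if true_log_odds is not None:
                row["true_log_odds"] = float(true_log_odds[i])
            fh.write(json.dumps(row, sort_keys=True) + "\n")


def read_cohort(
    path: str | Path,
) -> tuple[list[PatientRecord], CohortSpec | None, np.ndarray | None]:
    """Read a JSONL cohort; returns (records, spec or None, truth table or None)."""
    path = Path(path)
    records: list[PatientRecord] = []
    truths: list[float] = []
    spec: CohortSpec | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CohortParseError(f"line {lineno}: malformed JSON ({exc})") from exc
            if lineno == 1:
                if obj.get("format") != "bgpseq-cohort-v1":
                    raise CohortParseError("line 1: missing cohort header")
                if "spec" in obj:
                    sp = dict(obj["spec"])
                    sp["risk_tokens"] = {int(k): v for k, v in sp["risk_tokens"].items()}
                    sp["n_visits_range"] = tuple(sp["n_visits_range"])
                    sp["codes_per_visit_range"] = tuple(sp["codes_per_visit_range"])
                    spec = CohortSpec(**sp)
                continue
            try:
                records.append(
                    PatientRecord(
                        codes=list(obj["codes"]),
                        ages=list(obj["ages"]),
                        segments=list(obj["segments"]),
                        positions=list(obj["positions"]),
                        label=int(obj["label"]),
                    )
                )
            except (KeyError, TypeError) as exc:
                raise CohortParseError(f"line {lineno}: missing field ({exc})") from exc
            if "true_log_odds" in obj:
                truths.append(float(obj["true_log_odds"]))
    truth = np.asarray(truths) if len(truths) == len(records) and records else None
    return records, spec, truth


def max_record_length(records: list[PatientRecord]) -> int:
    return max((len(r) for r in records), default=0)
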