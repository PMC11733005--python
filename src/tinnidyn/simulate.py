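"""Synthetic 12-week diary cohorts with known ground truth.

Emulates the trial's measurement design: each patient answers ten 0-100
VAS questions once per evening over 84 days, with all-or-none daily
submission and patient-level compliance heterogeneity. The ordinal outcome
(CGI-I, 1..7) is drawn first from a latent standard-normal improvement
score thresholded at cutpoints implied by the category probabilities; the
diary trajectories are then generated from a signed severity score
s = CGI - 4 (0 at "no change"):

    value_qt = clip(mu_q + b_q * s * t + eps_t, 0, 100)

so improvers (s < 0) show declining symptom trends when b_q > 0 and rising
happiness when b_q < 0. For t-loudness the noise sd evolves over time as
sigma * exp(v * s * (t/83 - 1/2)), shrinking for improvers — a planted
variance-dynamics (lumpiness) signal. Days are dropped jointly across all
ten questions with probability 1 - c_i, c_i ~ Beta(a, b) with mean ~0.78.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .diary import N_DAYS, QUESTION_CODES, CgiOutcome, PatientDiary

#: Default CGI-I category probabilities (categories 1..7).
DEFAULT_CLASS_PROBS: tuple[float, ...] = (0.03, 0.17, 0.26, 0.39, 0.14, 0.01, 0.0)

#: Per-question VAS baselines.
DEFAULT_BASELINES: dict[str, float] = {
    "t-distress": 55.0,
    "t-distress-day": 55.0,
    "t-loudness": 60.0,
    "t-loudness-max": 65.0,
    "t-thoughts": 50.0,
    "happiness": 55.0,
    "jawbone": 40.0,
    "movement": 50.0,
    "neck": 45.0,
    "stress": 45.0,
}

#: Daily trend per unit severity (VAS points/day); positive entries rise
#: with worsening, the happiness entry falls. The three headline signals
#: (t-thoughts, jawbone, happiness) are strongest.
DEFAULT_SLOPES: dict[str, float] = {
    "t-distress": 0.0,
    "t-distress-day": 0.06,
    "t-loudness": 0.06,
    "t-loudness-max": 0.06,
    "t-thoughts": 0.15,
    "happiness": -0.15,
    "jawbone": 0.15,
    "movement": 0.0,
    "neck": 0.0,
    "stress": 0.0,
}


@dataclass
class SyntheticConfig:
    """Generative parameters of the synthetic cohort.

    Defaults mirror the measurement design: 84 daily all-or-none entries,
    CGI-I distribution peaked at "no change" with no category-7 patients,
    Beta-distributed compliance with mean ~0.78 and sd ~0.14.
    """

    n_patients: int = 300
    class_probs: tuple[float, ...] = DEFAULT_CLASS_PROBS
    baselines: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    slopes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SLOPES))
    noise_sd: float = 8.0
    #: exponential variance-dynamics factor applied to these questions
    variance_dynamics: dict[str, float] = field(
        default_factory=lambda: {"t-loudness": 0.6}
    )
    #: Beta(a, b) for per-patient compliance; mean 0.78, sd ~0.14
    compliance_a: float = 6.05
    compliance_b: float = 1.71
    #: optional AR(1) coefficient for the daily noise (0 = independent)
    ar1: float = 0.0
    seed: int = 17

    def __post_init__(self) -> None:
        probs = np.asarray(self.class_probs, dtype=float)
        if probs.size != 7 or not np.isclose(probs.sum(), 1.0):
            raise ValueError("class_probs must be 7 probabilities summing to 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated cohort, for recovery tests."""

    config: SyntheticConfig
    seed: int
    latent: np.ndarray  # per-patient latent improvement u
    cgi: np.ndarray
    compliance_probs: np.ndarray
    realized_slopes: dict[str, np.ndarray]  # per question: b_q * s per patient
    kept_days: list[np.ndarray]

    def to_json(self) -> str:
        d = {
            "seed": self.seed,
            "n_patients": self.config.n_patients,
            "latent": self.latent.tolist(),
            "cgi": self.cgi.tolist(),
            "compliance_probs": self.compliance_probs.tolist(),
            "realized_slopes": {q: v.tolist() for q, v in self.realized_slopes.items()},
            "kept_days": [d_.tolist() for d_ in self.kept_days],
        }
        return json.dumps(d, indent=1)


def _cutpoints(class_probs) -> np.ndarray:
    cum = np.cumsum(np.asarray(class_probs, dtype=float))[:-1]
    return stats.norm.ppf(np.clip(cum, 0.0, 1.0))


def generate(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[list[PatientDiary], list[CgiOutcome], SyntheticTruth]:
    """Generate a cohort; bit-identical for identical (config, seed)."""
    config = config or SyntheticConfig()
    seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    cuts = _cutpoints(config.class_probs)
    t = np.arange(N_DAYS, dtype=float)

    diaries: list[PatientDiary] = []
    outcomes: list[CgiOutcome] = []
    u = rng.standard_normal(config.n_patients)
    cgi = np.searchsorted(cuts, u) + 1
    comp = rng.beta(config.compliance_a, config.compliance_b, config.n_patients)
    realized: dict[str, np.ndarray] = {q: np.empty(config.n_patients) for q in QUESTION_CODES}
    kept_all: list[np.ndarray] = []

    width = len(str(max(config.n_patients - 1, 1)))
    for i in range(config.n_patients):
        s = float(cgi[i] - 4)
        keep = rng.random(N_DAYS) < comp[i]
        kept = np.flatnonzero(keep)
        kept_all.append(kept)
        series: dict[str, list[tuple[int, float]]] = {}
        for q in QUESTION_CODES:
            b = config.slopes.get(q, 0.0)
            realized[q][i] = b * s
            sd = np.full(N_DAYS, config.noise_sd)
            v = config.variance_dynamics.get(q, 0.0)
            if v:
                sd = sd * np.exp(v * s * (t / (N_DAYS - 1) - 0.5))
            eps = rng.standard_normal(N_DAYS) * sd
            if config.ar1:
                phi = config.ar1
                for k in range(1, N_DAYS):
                    eps[k] += phi * eps[k - 1]
            vals = np.clip(config.baselines[q] + b * s * t + eps, 0.0, 100.0)
            series[q] = [(int(d), float(vals[d])) for d in kept]
        pid = f"P{i:0{width}d}"
        diaries.append(PatientDiary(patient_id=pid, series=series))
        outcomes.append(CgiOutcome(patient_id=pid, cgi=int(cgi[i])))

    truth = SyntheticTruth(
        config=config,
        seed=seed,
        latent=u,
        cgi=cgi,
        compliance_probs=comp,
        realized_slopes=realized,
        kept_days=kept_all,
    )
    return diaries, outcomes, truth


DEMO_SEED = 49


def write_demo(outdir) -> dict[str, Path]:
    """Write a small fixed-seed cohort (n=60) as diary.csv/cgi.csv/truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = SyntheticConfig(n_patients=60, seed=DEMO_SEED)
    diaries, outcomes, truth = generate(config)
    paths = {
        "diary": outdir / "diary.csv",
        "cgi": outdir / "cgi.csv",
        "truth": outdir / "truth.json",
    }
    with open(paths["diary"], "w") as fh:
        fh.write("patient_id,day,question,value\n")
        for p in diaries:
            for q in QUESTION_CODES:
                for day, val in p.series[q]:
                    fh.write(f"{p.patient_id},{day},{q},{val:.4f}\n")
    with open(paths["cgi"], "w") as fh:
        fh.write("patient_id,cgi\n")
        for o in outcomes:
            fh.write(f"{o.patient_id},{o.cgi}\n")
    paths["truth"].write_text(truth.to_json())
    return paths
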