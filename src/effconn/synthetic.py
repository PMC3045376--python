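"""Synthetic block-design BOLD cohorts driven by condition-specific structural networks.

This module generates everything the downstream stages consume when no real
acquisition is available: a timed, categorised stimulus paradigm; a
four-node linear structural network per condition (frontal pole FP, left
posterior superior temporal sulcus pSTS, posterior cingulate/precuneus PCC,
rostral anterior cingulate rACC); HRF-convolved BOLD with measurement
noise; and a cohort of subjects whose behaviour score (a moral-judgment
ability scale in the 300-400 range) is linearly linked to selected path
strengths.

The generative story: at each scan the active stimulus category selects a
path-coefficient matrix B and residual variances psi; neural activity is
the instantaneous structural equilibrium x = (I - B)^-1 e with innovations
e ~ N(0, diag(psi)); each node's neural series is convolved with the
canonical double-gamma HRF and white measurement noise is added.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "CATEGORIES",
    "DEFAULT_DESIGN",
    "DEFAULT_ROIS",
    "REFERENCE_PATH_COEFFICIENTS",
    "Segment",
    "Paradigm",
    "GeneratingModel",
    "ROITimeSeries",
    "SubjectRecord",
    "make_paradigm",
    "canonical_hrf",
    "simulate_subject",
    "simulate_cohort",
    "default_generating_model",
    "reference_path_model_edges",
]

#: Stimulus categories of the block design (two moral, two non-moral, one neutral).
CATEGORIES = ("care", "justice", "neutral", "strategic", "tactical")

#: Default segment counts: 6 care + 6 justice moral issues, 6 strategic +
#: 6 tactical non-moral issues, 17 neutral segments -> 41 segments total.
DEFAULT_DESIGN = {"care": 6, "justice": 6, "neutral": 17, "strategic": 6, "tactical": 6}

#: The four network nodes, in canonical order.
DEFAULT_ROIS = ("FP", "pSTS", "PCC", "rACC")

# Group-level path coefficients (rows = target, cols = source) for the three
# modelled conditions; these published group estimates define the default
# generating connectivity.  Entries are 0 where no path was significant.
_REF = {
    "neutral": {
        ("FP", "pSTS"): -0.062,
        ("FP", "rACC"): 1.04,
        ("pSTS", "FP"): 0.913,
        ("PCC", "FP"): 0.205,
        ("PCC", "pSTS"): 0.943,
        ("rACC", "pSTS"): 1.11,
    },
    "care": {
        ("FP", "pSTS"): 1.09,
        ("pSTS", "FP"): 0.918,
        ("PCC", "FP"): 0.185,
        ("PCC", "pSTS"): 0.965,
        ("rACC", "PCC"): 0.299,
        ("rACC", "FP"): 0.885,
        ("rACC", "pSTS"): -0.205,
    },
    "justice": {
        ("FP", "pSTS"): 1.08,
        ("pSTS", "FP"): 3.72,
        ("pSTS", "PCC"): 1.36,
        ("pSTS", "rACC"): -4.18,
        ("PCC", "pSTS"): 0.945,
        ("PCC", "rACC"): 0.201,
        ("rACC", "pSTS"): 1.1,
    },
}


def _ref_matrix(condition: str, rois=DEFAULT_ROIS) -> pd.DataFrame:
    B = pd.DataFrame(0.0, index=list(rois), columns=list(rois))
    for (tgt, src), beta in _REF[condition].items():
        B.loc[tgt, src] = beta
    return B


#: Reference group path-coefficient matrices per condition (target x source).
REFERENCE_PATH_COEFFICIENTS = {c: _ref_matrix(c) for c in ("neutral", "care", "justice")}


def reference_path_model_edges(condition: str) -> list[tuple[str, str]]:
    """Directed edges (source, target) of the reference model for *condition*."""
    B = REFERENCE_PATH_COEFFICIENTS[condition]
    return sorted(
        (src, tgt) for tgt in B.index for src in B.columns if B.loc[tgt, src] != 0.0
    )


# --------------------------------------------------------------------------
# Paradigm
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    onset: float
    duration: float
    category: str


@dataclass(frozen=True)
class Paradigm:
    """Timed, categorised stimulus segments plus the scan grid they cover."""

    segments: tuple[Segment, ...]
    tr: float
    n_scans: int

    def __post_init__(self):
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.n_scans < 1:
            raise ValueError("n_scans must be >= 1")
        prev_end = -np.inf
        prev_onset = -np.inf
        for seg in self.segments:
            if seg.category not in CATEGORIES:
                raise ValueError(f"unknown category {seg.category!r}")
            if seg.duration <= 0:
                raise ValueError("every segment duration must be > 0")
            if seg.onset <= prev_onset:
                raise ValueError("segment onsets must be strictly increasing")
            if seg.onset < prev_end - 1e-9:
                raise ValueError("segments must not overlap")
            prev_onset, prev_end = seg.onset, seg.onset + seg.duration
        if self.segments and self.n_scans * self.tr < prev_end - 1e-9:
            raise ValueError("n_scans * tr must cover the last segment")

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for seg in self.segments:
            out[seg.category] = out.get(seg.category, 0) + 1
        return out

    @property
    def total_stimulus_duration(self) -> float:
        return float(sum(seg.duration for seg in self.segments))

    def scan_times(self) -> np.ndarray:
        return np.arange(self.n_scans) * self.tr

    def category_per_scan(self) -> np.ndarray:
        """Category label active at each scan time ('' outside any segment)."""
        cats = np.full(self.n_scans, "", dtype=object)
        t = self.scan_times()
        for seg in self.segments:
            cats[(t >= seg.onset - 1e-9) & (t < seg.onset + seg.duration - 1e-9)] = seg.category
        return cats

    def boxcar(self, category: str) -> np.ndarray:
        return (self.category_per_scan() == category).astype(float)

    def segments_of(self, category: str) -> list[Segment]:
        return [s for s in self.segments if s.category == category]


def make_paradigm(
    design_counts: dict[str, int] | None = None,
    segment_duration: float = 15.0,
    tr: float = 2.0,
    seed: int = 0,
    tail: float = 16.0,
) -> Paradigm:
    """Build a block paradigm of same-category segment pairs separated by neutrals.

    Non-neutral categories are presented as adjacent same-category pairs; a
    neutral segment separates consecutive pairs.  Neutral segments beyond the
    mandatory separators are placed at the start or end of the sequence,
    chosen reproducibly under *seed* (which also shuffles the pair order).
    *tail* seconds of scan time are appended after the last segment so that
    delayed-window block extraction and the HRF tail stay on the scan grid.
    """
    counts = dict(DEFAULT_DESIGN if design_counts is None else design_counts)
    if segment_duration <= 0:
        raise ValueError("segment_duration must be > 0")
    if tr <= 0:
        raise ValueError("tr must be > 0")
    for cat, c in counts.items():
        if cat not in CATEGORIES:
            raise ValueError(f"unknown category {cat!r}")
        if c < 0:
            raise ValueError("counts must be non-negative")

    pairs: list[str] = []
    for cat in CATEGORIES:
        if cat == "neutral":
            continue
        c = counts.get(cat, 0)
        if c % 2:
            raise ValueError(f"category {cat!r} has odd count {c}; pairs required")
        pairs.extend([cat] * (c // 2))

    n_neutral = counts.get("neutral", 0)
    n_separators = max(len(pairs) - 1, 0)
    if n_neutral < n_separators:
        raise ValueError(
            f"need at least {n_separators} neutral separators, got {n_neutral}"
        )
    surplus = n_neutral - n_separators

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))

    seq: list[str] = []
    for k, idx in enumerate(order):
        if k > 0:
            seq.append("neutral")
        seq.extend([pairs[idx], pairs[idx]])
    for _ in range(surplus):
        if rng.random() < 0.5:
            seq.insert(0, "neutral")
        else:
            seq.append("neutral")

    segments = tuple(
        Segment(onset=i * segment_duration, duration=segment_duration, category=cat)
        for i, cat in enumerate(seq)
    )
    total = len(seq) * segment_duration
    n_scans = max(1, math.ceil((total + tail) / tr))
    return Paradigm(segments=segments, tr=tr, n_scans=n_scans)


# --------------------------------------------------------------------------
# Hemodynamic response
# --------------------------------------------------------------------------


def canonical_hrf(
    tr: float,
    length: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_dispersion: float = 1.0,
    undershoot_dispersion: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled at *tr*, scaled to unit peak.

    Difference of two gamma densities: a positive response peaking near
    ``peak_delay`` seconds and an undershoot near ``undershoot_delay``
    seconds down-weighted by ``undershoot_ratio``.
    """
    if tr <= 0:
        raise ValueError("tr must be > 0")
    if length < tr:
        raise ValueError("length must be >= tr")
    t = np.arange(0.0, length, tr)
    peak = _gamma_dist.pdf(t, peak_delay / peak_dispersion, scale=peak_dispersion)
    under = _gamma_dist.pdf(
        t, undershoot_delay / undershoot_dispersion, scale=undershoot_dispersion
    )
    h = peak - undershoot_ratio * under
    return h / np.max(h)


# --------------------------------------------------------------------------
# Generating model and subjects
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ROITimeSeries:
    """BOLD samples (scans x labelled ROIs) at a fixed sampling interval."""

    data: pd.DataFrame
    tr: float

    @property
    def n_scans(self) -> int:
        return len(self.data)

    @property
    def rois(self) -> tuple[str, ...]:
        return tuple(self.data.columns)


@dataclass
class GeneratingModel:
    """Condition-specific linear structural networks driving synthetic BOLD.

    ``B_by_condition[c]`` is the path-coefficient matrix (target x source,
    zero diagonal) active during segments of condition ``c``;
    ``Psi_by_condition[c]`` the innovation variances.  ``behavior_link``
    maps selected generating paths, as ``(condition, source, target)``, to a
    slope on the behaviour score.
    """

    nodes: tuple[str, ...]
    B_by_condition: dict[str, np.ndarray]
    Psi_by_condition: dict[str, np.ndarray]
    noise_sd: float = 1.0
    subject_sd: float = 0.2
    behavior_link: tuple[tuple[tuple[str, str, str], float], ...] = ()
    score_base: float = 350.0
    score_sd: float = 20.0

    def __post_init__(self):
        p = len(self.nodes)
        self.B_by_condition = {
            c: np.asarray(B, dtype=float) for c, B in self.B_by_condition.items()
        }
        self.Psi_by_condition = {
            c: np.asarray(v, dtype=float) for c, v in self.Psi_by_condition.items()
        }
        for c, B in self.B_by_condition.items():
            if B.shape != (p, p):
                raise ValueError(f"B for {c!r} must be {p}x{p}")
            if np.any(np.diag(B) != 0):
                raise ValueError(f"B for {c!r} has nonzero diagonal (self-loops)")
            if np.linalg.svd(np.eye(p) - B, compute_uv=False)[-1] <= 1e-8:
                raise ValueError(f"I - B is numerically singular for condition {c!r}")
        for c, v in self.Psi_by_condition.items():
            if v.shape != (p,):
                raise ValueError(f"Psi for {c!r} must have length {p}")
            if np.any(v <= 0):
                raise ValueError(f"Psi for {c!r} must be strictly positive")

    def conditions(self) -> tuple[str, ...]:
        return tuple(self.B_by_condition)


@dataclass
class SubjectRecord:
    """One simulated subject: BOLD series, behaviour score, generating truth."""

    subject_id: str
    timeseries: ROITimeSeries
    score: float
    true_paths: dict[str, pd.DataFrame]
    neural: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if not np.isfinite(self.score):
            raise ValueError("score must be finite")


def default_generating_model(
    stabilize: float = 0.7,
    noise_sd: float = 1.0,
    subject_sd: float = 0.2,
    score_sd: float = 20.0,
) -> GeneratingModel:
    """The default four-node generating model built from the reference networks.

    Reciprocal path pairs in the reference matrices carry near- or
    super-unit loop gains (e.g. the care-condition pSTS<->FP loop,
    1.09 x 0.918 ~ 1.0006), which would make I - B near-singular; both
    members of every reciprocal pair are therefore rescaled by *stabilize*.
    Strategic and tactical segments reuse the neutral network.  The default
    behaviour link puts a negative slope on the justice-condition pSTS->PCC
    path, sized so that under default between-subject jitter the linked path
    accounts for ~60% of the score variance.
    """
    rois = DEFAULT_ROIS
    idx = {r: i for i, r in enumerate(rois)}
    B_by, Psi_by = {}, {}
    for cond in ("neutral", "care", "justice"):
        B = REFERENCE_PATH_COEFFICIENTS[cond].to_numpy().copy()
        for i in range(len(rois)):
            for j in range(i + 1, len(rois)):
                if B[i, j] != 0 and B[j, i] != 0:  # reciprocal pair
                    B[i, j] *= stabilize
                    B[j, i] *= stabilize
        B_by[cond] = B
        Psi_by[cond] = np.ones(len(rois))
    B_by["strategic"] = B_by["neutral"].copy()
    B_by["tactical"] = B_by["neutral"].copy()
    Psi_by["strategic"] = Psi_by["neutral"].copy()
    Psi_by["tactical"] = Psi_by["neutral"].copy()

    # slope * subject_sd = sqrt(1.5) * score_sd  =>  linked path explains 60%
    # of score variance at the generating level.
    slope = -math.sqrt(1.5) * score_sd / subject_sd if subject_sd > 0 else -122.5
    # offset the base so the cohort mean score sits at 350 (scores ~300-400)
    linked_mean = B_by["justice"][idx["PCC"], idx["pSTS"]]
    return GeneratingModel(
        nodes=rois,
        B_by_condition=B_by,
        Psi_by_condition=Psi_by,
        noise_sd=noise_sd,
        subject_sd=subject_sd,
        behavior_link=((("justice", "pSTS", "PCC"), slope),),
        score_base=350.0 - slope * linked_mean,
        score_sd=score_sd,
    )


_BASELINE = "__baseline__"


def simulate_subject(
    model: GeneratingModel,
    paradigm: Paradigm,
    seed,
    subject_id: str = "sub-01",
) -> SubjectRecord:
    """Simulate one subject's ROI BOLD series and behaviour score.

    Innovations are drawn per scan with the variance of the active
    condition; outside any segment the neutral variances apply with B = 0.
    Neural activity solves x = (I - B_c)^-1 e scan-wise, is convolved with
    the canonical HRF per node, and receives white measurement noise.
    """
    rng = np.random.default_rng(seed)
    p = len(model.nodes)
    cats = paradigm.category_per_scan()
    for cat in set(cats) - {""}:
        if cat not in model.B_by_condition:
            raise ValueError(f"paradigm condition {cat!r} unknown to the model")

    z = rng.standard_normal((paradigm.n_scans, p))
    noise = rng.normal(0.0, model.noise_sd, size=(paradigm.n_scans, p))
    score_noise = rng.normal(0.0, model.score_sd)

    neutral_psi = model.Psi_by_condition.get("neutral", np.ones(p))
    x = np.empty_like(z)
    labels = np.where(cats == "", _BASELINE, cats)
    for cond in np.unique(labels):
        sel = labels == cond
        if cond == _BASELINE:
            x[sel] = z[sel] * np.sqrt(neutral_psi)
        else:
            e = z[sel] * np.sqrt(model.Psi_by_condition[cond])
            A = np.eye(p) - model.B_by_condition[cond]
            x[sel] = np.linalg.solve(A, e.T).T

    h = canonical_hrf(paradigm.tr)
    bold = np.empty_like(x)
    for j in range(p):
        bold[:, j] = np.convolve(x[:, j], h)[: paradigm.n_scans]
    bold += noise

    score = model.score_base + score_noise
    for (cond, src, tgt), slope in model.behavior_link:
        i, j = model.nodes.index(tgt), model.nodes.index(src)
        score += slope * model.B_by_condition[cond][i, j]

    data = pd.DataFrame(bold, columns=list(model.nodes))
    true_paths = {
        c: pd.DataFrame(B.copy(), index=list(model.nodes), columns=list(model.nodes))
        for c, B in model.B_by_condition.items()
    }
    return SubjectRecord(
        subject_id=subject_id,
        timeseries=ROITimeSeries(data=data, tr=paradigm.tr),
        score=float(score),
        true_paths=true_paths,
        neural=x,
    )


def _jittered(model: GeneratingModel, rng: np.random.Generator) -> GeneratingModel:
    B_by = {}
    for c, B in model.B_by_condition.items():
        mask = B != 0
        jitter = rng.normal(0.0, model.subject_sd, size=B.shape) * mask
        B_by[c] = B + jitter
    return GeneratingModel(
        nodes=model.nodes,
        B_by_condition=B_by,
        Psi_by_condition={c: v.copy() for c, v in model.Psi_by_condition.items()},
        noise_sd=model.noise_sd,
        subject_sd=model.subject_sd,
        behavior_link=model.behavior_link,
        score_base=model.score_base,
        score_sd=model.score_sd,
    )


def simulate_cohort(
    model: GeneratingModel,
    paradigm: Paradigm,
    n_subjects: int = 17,
    seed: int = 0,
) -> list[SubjectRecord]:
    """Simulate independent subjects with per-subject path-coefficient jitter."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    records = []
    for i, child in enumerate(children):
        jit_seed, sim_seed = child.spawn(2)
        subj_model = _jittered(model, np.random.default_rng(jit_seed))
        records.append(
            simulate_subject(
                subj_model, paradigm, sim_seed, subject_id=f"sub-{i + 1:02d}"
            )
        )
    return records
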