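"""Cohort-level PID pipeline, surrogate normalization and group statistics.

Orchestrates, per subject and neural node: band-pass filtering into the
syllable-rate band, Hilbert transform, 100 ms stimulus-to-brain lag
alignment, the 2D phase representation, copula normalization, the 6x6
joint covariance, and the four-term PID.  A surrogate twin of every map
is computed with time-shifted stimuli (auditory shifted 60 s, visual
30 s, circularly) to estimate the analysis bias; subtracting it within
subject yields the normalized maps entering group statistics.

Group statistics operate at node level: paired t statistics with
sign-flip permutation p-values, regression of each information map on
the behavioral score with score-shuffling permutation, t-to-Z
conversion by two-sided tail-probability matching, Z-map differences
between conditions, and Benjamini-Hochberg FDR across nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

from .gcmi import copula_normalise
from .pid import pid_decompose
from .signal_prep import TimeSeries, bandpass_analytic, lag_align, phase_2d, trim_edges
from .synthetic import SubjectDataset

__all__ = [
    "PipelineConfig",
    "CohortInfoMaps",
    "ContrastResult",
    "time_shift_surrogate",
    "run_pid_pipeline",
    "surrogate_normalise",
    "group_contrast",
    "behavior_regression_z",
    "behavior_correlation",
    "fdr_bh",
]

PID_TERMS = ("red", "uni_a", "uni_v", "syn")


@dataclass
class PipelineConfig:
    """Analysis settings of the PID pipeline."""

    band_center: float = 5.0
    band_halfwidth: float = 2.0
    lag_ms: float = 100.0
    shift_a_s: float = 60.0
    shift_v_s: float = 30.0
    trim_s: float = 1.0
    n_mc: int = 50_000
    rng_seed: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class CohortInfoMaps:
    """Per subject x node PID terms with a surrogate twin of the same shape."""

    main: pd.DataFrame
    surrogate: pd.DataFrame
    condition: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for df in (self.main, self.surrogate):
            missing = {"subject", "node", *PID_TERMS} - set(df.columns)
            if missing:
                raise ValueError(f"map table missing columns {sorted(missing)}")
        if self.main.shape[0] != self.surrogate.shape[0]:
            raise ValueError("main and surrogate maps must share shape")
        if set(self.main["node"]) != set(self.surrogate["node"]):
            raise ValueError("main and surrogate maps must share node labels")


@dataclass
class ContrastResult:
    """Per-node statistics table plus the thresholds that produced it."""

    table: pd.DataFrame
    alpha: float
    multiplicity: str = "fdr_bh"


def time_shift_surrogate(
    audio_env: TimeSeries, lip_area: TimeSeries, shift_a_s: float = 60.0, shift_v_s: float = 30.0
) -> tuple[TimeSeries, TimeSeries]:
    """Circularly shift the stimuli (auditory 60 s, visual 30 s by default).

    The shifts destroy the stimulus-brain alignment while preserving
    each signal's spectrum and length; neural data are untouched.
    """
    for name, shift, ts in (("auditory", shift_a_s, audio_env), ("visual", shift_v_s, lip_area)):
        if shift >= ts.duration:
            raise ValueError(f"{name} shift of {shift} s is not shorter than the {ts.duration} s series")
    a = np.roll(audio_env.values, int(round(shift_a_s * audio_env.fs)))
    v = np.roll(lip_area.values, int(round(shift_v_s * lip_area.fs)))
    return (
        TimeSeries(a, audio_env.fs, audio_env.label + "_shifted"),
        TimeSeries(v, lip_area.fs, lip_area.label + "_shifted"),
    )


def _phase_block(ts: TimeSeries, cfg: PipelineConfig) -> np.ndarray:
    s = bandpass_analytic(ts, cfg.band_center, cfg.band_halfwidth)
    vals = trim_edges(s.values, ts.fs, cfg.trim_s)
    p = phase_2d(type(s)(vals, ts.fs, cfg.band_center, cfg.band_halfwidth))
    return np.column_stack([p.x, p.y])


def _subject_pid(
    audio: TimeSeries, lip: TimeSeries, node: TimeSeries, cfg: PipelineConfig, seed: int
) -> dict[str, float]:
    xa = _phase_block(audio, cfg)
    xv = _phase_block(lip, cfg)
    xm = _phase_block(node, cfg)
    stim, m = lag_align(np.concatenate([xa, xv], axis=1), xm, cfg.lag_ms, node.fs)
    cm = copula_normalise(np.concatenate([m, stim], axis=1))
    res = pid_decompose(cm.data[:, :2], cm.data[:, 2:4], cm.data[:, 4:6], n_mc=cfg.n_mc, rng_seed=seed)
    return {
        "red": res.red, "uni_a": res.uni_a, "uni_v": res.uni_v, "syn": res.syn,
        "mi_a": res.mi_a, "mi_v": res.mi_v, "mi_av": res.mi_av, "mc_se": res.mc_se,
    }


def run_pid_pipeline(
    cohort: list[SubjectDataset], config: PipelineConfig | None = None, condition: str = ""
) -> CohortInfoMaps:
    """PID maps for every subject and node, with their surrogate twins."""
    cfg = config or PipelineConfig()
    rows, srows = [], []
    base = np.random.SeedSequence(cfg.rng_seed)
    for subj, ss in zip(cohort, base.spawn(len(cohort))):
        seeds = ss.generate_state(2 * len(subj.nodes)) >> 1  # keep below 2**31
        a_sur, v_sur = time_shift_surrogate(subj.audio_env, subj.lip_area, cfg.shift_a_s, cfg.shift_v_s)
        for i, (name, node) in enumerate(subj.nodes.items()):
            meta = {"subject": subj.subject_id, "node": name, "kind": subj.node_kinds.get(name, "")}
            rows.append(meta | _subject_pid(subj.audio_env, subj.lip_area, node, cfg, int(seeds[2 * i])))
            srows.append(meta | _subject_pid(a_sur, v_sur, node, cfg, int(seeds[2 * i + 1])))
    return CohortInfoMaps(
        main=pd.DataFrame(rows),
        surrogate=pd.DataFrame(srows),
        condition=condition,
        provenance={"config": cfg.as_dict(), "n_subjects": len(cohort)},
    )


def surrogate_normalise(maps: CohortInfoMaps) -> pd.DataFrame:
    """Subtract the surrogate map from the main map within subject/node/term."""
    keys = ["subject", "node"]
    cols = [c for c in ("red", "uni_a", "uni_v", "syn", "mi_a", "mi_v", "mi_av") if c in maps.main.columns]
    main = maps.main.set_index(keys)
    sur = maps.surrogate.set_index(keys)
    out = main.copy()
    out[cols] = main[cols] - sur[cols]
    return out.reset_index()


def dominant_term(maps: pd.DataFrame) -> pd.Series:
    """Argmax PID term per row of a (normalized) map table.

    Used to label each node's coupling kind from its decomposition:
    redundant -> 'red', unique -> 'uni_a'/'uni_v', synergistic -> 'syn'.
    """
    return maps[list(PID_TERMS)].idxmax(axis=1)


def _pivot(df: pd.DataFrame, term: str) -> pd.DataFrame:
    return df.pivot(index="subject", columns="node", values=term)


def group_contrast(
    maps_a: pd.DataFrame,
    maps_b: pd.DataFrame,
    term: str = "red",
    paired: bool = True,
    n_perm: int = 5000,
    alpha: float = 0.05,
    rng_seed: int = 0,
) -> ContrastResult:
    """Per-node paired t with sign-flip permutation p and FDR mask.

    ``maps_a``/``maps_b`` are normalized map tables (subject, node,
    terms); subjects must match when ``paired``.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be at least 2 for a non-degenerate null")
    if not paired:
        raise NotImplementedError("only the paired (dependent-samples) contrast is provided")
    a = _pivot(maps_a, term)
    b = _pivot(maps_b, term)
    if not a.index.equals(b.index):
        raise ValueError("paired contrast requires matched subjects")
    diff = (a - b[a.columns]).to_numpy()
    n, k = diff.shape
    sd = diff.std(0, ddof=1)
    sd = np.where(sd == 0, np.inf, sd)  # identical maps -> t = 0, p = 1
    t_obs = diff.mean(0) / (sd / np.sqrt(n))
    rng = np.random.default_rng(rng_seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    perm = signs @ diff / n  # permuted means, shape (n_perm, k)
    perm_t = perm / (sd / np.sqrt(n))
    # the observed labelling is one member of the permutation distribution
    p = (np.sum(np.abs(perm_t) >= np.abs(t_obs), axis=0) + 1) / (n_perm + 1)
    z = t_to_z(t_obs, df=n - 1)
    sig = fdr_bh(p, alpha)
    table = pd.DataFrame({"node": a.columns, "t": t_obs, "p": p, "z": z, "significant": sig})
    return ContrastResult(table=table, alpha=alpha, multiplicity="fdr_bh")


def t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Convert t statistics to standard Z by two-sided tail-probability matching."""
    t = np.asarray(t, dtype=float)
    p_two = 2.0 * sst.t.sf(np.abs(t), df)
    return np.sign(t) * sst.norm.isf(np.clip(p_two, 1e-300, 1.0) / 2.0)


def behavior_regression_z(
    maps_by_condition: dict[str, pd.DataFrame],
    scores: np.ndarray,
    term: str = "red",
    n_perm: int = 5000,
    alpha: float = 0.005,
    rng_seed: int = 0,
    tail: str = "greater",
) -> ContrastResult:
    """Regress each node's information term on the behavioral score.

    Per condition and node: regression slope t, permutation p by score
    shuffling (one-sided for positive association by default, matching
    the detection of regions positively correlated with comprehension),
    and a Z value via tail-probability matching.  With two conditions,
    the table carries a ``z_difference`` column (first condition minus
    second), thresholded at ``alpha`` (default P < 0.005) on the
    per-condition permutation p.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be at least 2")
    if tail not in ("greater", "two-sided"):
        raise ValueError("tail must be 'greater' or 'two-sided'")
    scores = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(rng_seed)
    frames = {}
    for cond, df in maps_by_condition.items():
        vals = _pivot(df, term)
        n = vals.shape[0]
        if n != scores.size:
            raise ValueError("one score per subject is required")
        t_obs = _slope_t(vals.to_numpy(), scores)
        perm_t = np.empty((n_perm, vals.shape[1]))
        for i in range(n_perm):
            perm_t[i] = _slope_t(vals.to_numpy(), rng.permutation(scores))
        if tail == "greater":
            p = (np.sum(perm_t >= t_obs, axis=0) + 1) / (n_perm + 1)
        else:
            p = (np.sum(np.abs(perm_t) >= np.abs(t_obs), axis=0) + 1) / (n_perm + 1)
        frames[cond] = pd.DataFrame(
            {"node": vals.columns, "condition": cond, "t": t_obs, "p": p,
             "z": t_to_z(t_obs, df=n - 2), "significant": p < alpha}
        )
    table = pd.concat(frames.values(), ignore_index=True)
    conds = list(frames)
    if len(conds) == 2:
        za = frames[conds[0]].set_index("node")["z"]
        zb = frames[conds[1]].set_index("node")["z"]
        zdiff = (za - zb).rename("z_difference").reset_index()
        table = table.merge(zdiff, on="node", how="left")
    return ContrastResult(table=table, alpha=alpha, multiplicity="uncorrected")


def _slope_t(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """t statistic of the regression slope of each column of y on x."""
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean(0)
    sxx = np.sum(xc**2)
    slope = xc @ yc / sxx
    resid = yc - np.outer(xc, slope)
    se = np.sqrt(np.sum(resid**2, axis=0) / (n - 2) / sxx)
    return slope / se


def behavior_correlation(values: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """Across-subject Pearson correlation with two-sided p."""
    r, p = sst.pearsonr(np.asarray(values, float), np.asarray(scores, float))
    return float(r), float(p)


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject
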