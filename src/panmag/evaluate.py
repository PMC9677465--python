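"""Core-gene loss and recovery statistics.

Quantifies how the core genome shrinks under degradation (count curves and
the log-linear exponential decay fit ``y = exp(a*x + b)``), and how much of
it a relaxed core-gene threshold buys back: true/false positives of the
recovered core-gene set against the complete-genome reference, recall /
precision / F-score, and the coverage of threshold-induced core-gene gains.

Matching between a simulated and a reference core-gene set can use either
sequence identity between cluster representatives (``identity`` mode, the
analogue of searching representatives against each other) or the generator's
hidden family labels (``oracle_labels`` mode, exact ground truth on
synthetic data).  On divergence-separated synthetic data the two must
agree, which the test suite exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .errors import ConfigurationError
from .pangenome import PanGenome, _RepIndex, banded_identity, pairwise_identity
from .species import encode_seq


@dataclass(frozen=True)
class ExponentialFit:
    a: float  # decay rate per unit x
    b: float  # intercept on the log scale
    adjusted_r2: float
    p_value: float


@dataclass(frozen=True)
class CGComparison:
    tp: int
    fp: int
    recall: float | None
    precision: float | None
    f_score: float | None
    coverage_of_increased_cgs: float | None = None


def cg_count_curve(pan_genomes: list[tuple[float, "PanGenome | int"]]
                   ) -> list[tuple[float, int]]:
    """(level, core count) pairs ordered by level; duplicate levels are an error."""
    if len(pan_genomes) < 2:
        raise ConfigurationError("need at least two (level, pan-genome) points")
    levels = [lv for lv, _ in pan_genomes]
    if len(set(levels)) != len(levels):
        raise ConfigurationError("duplicate levels in curve input")
    series = [(lv, p.core_count if isinstance(p, PanGenome) else int(p))
              for lv, p in pan_genomes]
    return sorted(series)


def fit_exponential(xs, ys) -> ExponentialFit:
    """Fit ``y = exp(a*x + b)`` by ordinary least squares of ln(y) on x.

    ``adjusted_r2 = 1 - (1 - R^2)(n-1)/(n-2)``; the p-value is the two-sided
    t-test on the slope.  A perfectly flat series has slope 0 and p-value 1.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size < 3 or xs.size != ys.size:
        raise ConfigurationError("need >= 3 (x, y) points")
    if (ys <= 0).any():
        raise ConfigurationError("exponential fit requires positive y values")
    logy = np.log(ys)
    if np.ptp(logy) == 0.0:  # flat series: slope 0, R^2 undefined -> 0
        return ExponentialFit(a=0.0, b=float(logy[0]), adjusted_r2=0.0, p_value=1.0)
    res = sm.OLS(logy, sm.add_constant(xs)).fit()
    b, a = res.params
    p = float(res.pvalues[1])
    if np.isnan(p):
        p = 1.0 if abs(a) < 1e-12 else 0.0  # zero-residual degenerate cases
    return ExponentialFit(a=float(a), b=float(b),
                          adjusted_r2=float(res.rsquared_adj), p_value=p)


def replicate_summary(values) -> tuple[float, float, float]:
    """(mean, median, sample SD) of replicate core-gene counts."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ConfigurationError("need >= 2 replicate values")
    return float(values.mean()), float(np.median(values)), float(values.std(ddof=1))


# ---------------------------------------------------------------------------
# core-gene set matching
# ---------------------------------------------------------------------------

def _match_reps_identity(query_seqs: list[str], ref_seqs: list[str],
                         si: float, prefilter: bool = True) -> list[bool]:
    """For each query representative, does any reference representative match
    at >= si percent identity?"""
    threshold = si / 100.0 - 1e-9
    if not prefilter:
        return [any(pairwise_identity(q, r) >= threshold for r in ref_seqs)
                for q in query_seqs]
    index = _RepIndex(band=16)
    for r in ref_seqs:
        index.add(encode_seq(r))
    out = []
    for q in query_seqs:
        arr = encode_seq(q)
        hit = False
        for idx, diag in index.candidates(arr):
            if banded_identity(arr, index.seqs[idx], diag) >= threshold:
                hit = True
                break
        out.append(hit)
    return out


def _core_sets(pan: PanGenome):
    core = pan.clusters_in("core")
    seqs = [pan.representative_seqs[cid] for cid in core]
    fams = [pan.cluster_family[cid] for cid in core]
    return core, seqs, fams


def match_cg_sets(sim_pan: PanGenome, ref_pan: PanGenome, si: float | None = None,
                  mode: str = "identity", prefilter: bool = True) -> CGComparison:
    """TP/FP of the simulated core-gene set against the reference core-gene set.

    recall = TP / |reference core set|, precision = TP / |simulated core set|,
    F-score = their harmonic mean.  Undefined ratios are reported as None.
    """
    if mode not in ("identity", "oracle_labels"):
        raise ConfigurationError(f"unknown matching mode {mode!r}")
    si = sim_pan.si_threshold if si is None else si
    _, ref_seqs, ref_fams = _core_sets(ref_pan)
    if not ref_seqs:
        raise ConfigurationError("reference core-gene set is empty")
    _, sim_seqs, sim_fams = _core_sets(sim_pan)
    if mode == "oracle_labels":
        ref_set = set(ref_fams)
        matched = [f in ref_set for f in sim_fams]
    else:
        matched = _match_reps_identity(sim_seqs, ref_seqs, si, prefilter)
    tp = int(sum(matched))
    fp = len(matched) - tp
    recall = tp / len(ref_seqs)
    precision = tp / len(sim_seqs) if sim_seqs else None
    if precision is None or precision + recall == 0:
        f_score = None
    else:
        f_score = 2 * precision * recall / (precision + recall)
    return CGComparison(tp=tp, fp=fp, recall=recall, precision=precision,
                        f_score=f_score)


def coverage_of_increased_cgs(sim_pans: dict[float, PanGenome],
                              ref_pans: dict[float, PanGenome],
                              si: float | None = None, mode: str = "identity",
                              prefilter: bool = True) -> dict[float, float | None]:
    """Per relaxed threshold t: of the core genes the reference dataset gains
    when going from the 100% threshold to t, the fraction also gained by the
    simulated dataset.  ``None`` when the reference gains nothing (0/0)."""
    if 100.0 not in sim_pans or 100.0 not in ref_pans:
        raise ConfigurationError("both grids must contain the 100% baseline")

    def increased(pans, t):
        base = set(pans[100.0].clusters_in("core"))
        gained = [cid for cid in pans[t].clusters_in("core") if cid not in base]
        return gained

    out: dict[float, float | None] = {}
    for t in sorted(ref_pans):
        if t == 100.0 or t not in sim_pans:
            continue
        ref_gained = increased(ref_pans, t)
        sim_gained = increased(sim_pans, t)
        if not ref_gained:
            out[t] = None
            continue
        ref_pan, sim_pan = ref_pans[t], sim_pans[t]
        if mode == "oracle_labels":
            sim_fams = {sim_pan.cluster_family[cid] for cid in sim_gained}
            hit = [ref_pan.cluster_family[cid] in sim_fams for cid in ref_gained]
        else:
            use_si = ref_pan.si_threshold if si is None else si
            ref_seqs = [ref_pan.representative_seqs[cid] for cid in ref_gained]
            sim_seqs = [sim_pan.representative_seqs[cid] for cid in sim_gained]
            if not sim_seqs:
                out[t] = 0.0
                continue
            hit = _match_reps_identity(ref_seqs, sim_seqs, use_si, prefilter)
        out[t] = sum(hit) / len(ref_gained)
    return out
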