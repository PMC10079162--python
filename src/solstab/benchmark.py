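"""False-discovery-rate benchmark for stability predictions.

Given records pairing experimental and predicted stability changes
(negative ddG = stabilising after canonicalisation), a predicted
stabilising mutation that is destabilising in practice is a false
positive — in a design setting the costly kind of error, since it
wastes wet-lab effort.  This module classifies records into the four
sign quadrants, computes ``FDR = FP / (FP + TP)`` under optional
phylogenetic filters, and assesses filter-induced FDR reductions with
an explicit random-resampling significance test that separates the
effect of the filter from that of the mere reduction in dataset size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BenchmarkRecord:
    """One mutation with experimental and predicted ddG (kcal/mol)."""

    protein_id: str
    mutation: str
    ddg_exp: float  # negative = stabilising
    ddg_pred: float
    loglik_mut: float
    delta_loglik: float


@dataclass
class FdrResult:
    tp: int
    fp: int
    tn: int
    fn: int
    fdr: float
    filter_mode: str
    n_kept: int
    pvalue: Optional[float] = None


def read_benchmark_csv(
    path: str | Path, exp_sign_convention: str = "neg_stabilising"
) -> list[BenchmarkRecord]:
    """Load benchmark records, canonicalising to negative-stabilising.

    ``exp_sign_convention='pos_stabilising'`` flips the sign of both
    ddG columns (thermodynamic tables vary in their convention).
    """
    if exp_sign_convention not in ("neg_stabilising", "pos_stabilising"):
        raise ValueError(f"unknown sign convention {exp_sign_convention!r}")
    flip = -1.0 if exp_sign_convention == "pos_stabilising" else 1.0
    df = pd.read_csv(path)
    return [
        BenchmarkRecord(
            protein_id=str(r.protein_id),
            mutation=str(r.mutation),
            ddg_exp=flip * float(r.ddg_exp),
            ddg_pred=flip * float(r.ddg_pred),
            loglik_mut=float(r.loglik_mut),
            delta_loglik=float(r.delta_loglik),
        )
        for r in df.itertuples()
    ]


def write_benchmark_csv(records: Sequence[BenchmarkRecord], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, index=False)


def _filter_mask(records: Sequence[BenchmarkRecord], filter_mode, eps: float):
    if filter_mode == "none":
        return np.ones(len(records), dtype=bool)
    if filter_mode == "ll_pos":
        return np.array([r.loglik_mut > 0 for r in records])
    if filter_mode == "ll_and_delta":
        return np.array(
            [r.loglik_mut > 0 and r.delta_loglik > 0 for r in records]
        )
    if filter_mode == "abs_pred_ge":
        if eps is None:
            raise ValueError("abs_pred_ge filter needs eps")
        return np.array([abs(r.ddg_pred) >= eps for r in records])
    raise ValueError(f"unknown filter {filter_mode!r}")


def _counts(pred: np.ndarray, exp: np.ndarray) -> tuple[int, int, int, int]:
    # ddG exactly 0 counts as non-stabilising on both axes
    pred_stab = pred < 0
    exp_stab = exp < 0
    tp = int((pred_stab & exp_stab).sum())
    fp = int((pred_stab & ~exp_stab).sum())
    tn = int((~pred_stab & ~exp_stab).sum())
    fn = int((~pred_stab & exp_stab).sum())
    return tp, fp, tn, fn


def classify_and_fdr(
    records: Sequence[BenchmarkRecord],
    filter_mode: str = "none",
    eps: Optional[float] = None,
) -> FdrResult:
    """Quadrant counts and FDR of the records passing a filter.

    Filters: ``none``; ``ll_pos`` (mutant log-likelihood > 0);
    ``ll_and_delta`` (additionally delta log-likelihood > 0);
    ``abs_pred_ge`` with ``eps`` (drop predictions within ``eps`` of
    zero — the control for trivial near-zero removal).
    """
    mask = _filter_mask(records, filter_mode, eps)
    if not mask.any():
        raise ValueError(f"filter {filter_mode!r} keeps no records; FDR undefined")
    pred = np.array([r.ddg_pred for r in records])[mask]
    exp = np.array([r.ddg_exp for r in records])[mask]
    tp, fp, tn, fn = _counts(pred, exp)
    fdr = fp / (fp + tp) if (fp + tp) > 0 else 0.0
    label = filter_mode if eps is None else f"{filter_mode}({eps})"
    return FdrResult(tp, fp, tn, fn, fdr, label, int(mask.sum()))


def resampling_pvalue(
    records: Sequence[BenchmarkRecord],
    filter_mode: str,
    n_resample: int = 10000,
    seed: int = 0,
    eps: Optional[float] = None,
) -> float:
    """Significance of a filter's FDR against size-matched random subsets.

    Draws ``n_resample`` uniform subsets (without replacement) of the
    full record set, each of the filtered subset's size, and reports
    the add-one estimate ``p = (1 + #{FDR_subset <= FDR_observed}) /
    (n_resample + 1)`` — the probability that restricting to a random
    subset of the same size does at least as well as the filter.
    """
    observed = classify_and_fdr(records, filter_mode, eps)
    if observed.tp + observed.fp == 0:
        raise ValueError("filtered subset has no predicted-stabilising records")
    n = len(records)
    k = observed.n_kept
    if k > n:
        raise ValueError("subset size exceeds record count")

    pred_stab = np.array([r.ddg_pred < 0 for r in records])
    is_fp = pred_stab & np.array([r.ddg_exp >= 0 for r in records])

    rng = np.random.default_rng(seed)
    count = 0
    batch = max(1, min(n_resample, 2_000_000 // max(k, 1)))
    done = 0
    while done < n_resample:
        b = min(batch, n_resample - done)
        keys = rng.random((b, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        fp = is_fp[idx].sum(axis=1)
        pos = pred_stab[idx].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            fdr = np.where(pos > 0, fp / np.maximum(pos, 1), 0.0)
        count += int((fdr <= observed.fdr + 1e-12).sum())
        done += b
    return (1 + count) / (n_resample + 1)


def benchmark_report(
    records: Sequence[BenchmarkRecord],
    filters: Sequence[str] = ("none", "ll_pos", "ll_and_delta"),
    n_resample: int = 10000,
    seed: int = 0,
    eps: Optional[float] = None,
) -> pd.DataFrame:
    """FDR per filter, with resampling p-values for the non-trivial ones."""
    rows = []
    for f in filters:
        res = classify_and_fdr(records, f, eps if f == "abs_pred_ge" else None)
        if f != "none":
            res.pvalue = resampling_pvalue(
                records, f, n_resample=n_resample, seed=seed,
                eps=eps if f == "abs_pred_ge" else None,
            )
        rows.append(
            {
                "filter": res.filter_mode,
                "n_kept": res.n_kept,
                "TP": res.tp,
                "FP": res.fp,
                "TN": res.tn,
                "FN": res.fn,
                "FDR": res.fdr,
                "pvalue": res.pvalue,
            }
        )
    return pd.DataFrame(rows)
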