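"""ΔCt relative expression and coverage-based transcript annotation.

Relative expression follows the ΔCt method (no calibrator sample):
per replicate, ΔCt = Ct_target − Ct_reference and relative expression
is 2^(−ΔCt), summarised per sample as mean ± sd over replicates. A
target reaction that never amplifies is recorded with the literal
sentinel "UD" rather than an imputed cycle number; a sample whose
target is undetectable in at least half its replicates is reported as
expression 0 with an ``undetected`` flag — the signature of genotypes
with no intact copy of the gene. A reference-gene failure is a
technical error, not biology, and excludes the sample with an error
flag.

Transcript-unit annotation finds maximal runs of per-base read
coverage above a threshold, tolerating short sub-threshold gaps; the
locus transcript is intronless, so internal gaps are noise, not
splicing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionResult",
    "delta_ct",
    "call_transcribed_region",
]

UNDETECTED = "UD"
CT_MAX = 45.0


@dataclass(frozen=True)
class ExpressionResult:
    sample: str
    expression_mean: float
    expression_sd: float
    n_replicates: int
    detected: bool
    error: str | None = None  # "reference-failure" when the reference gene failed


def _validate_ct(value) -> float:
    ct = float(value)
    if not 0.0 < ct <= CT_MAX:
        raise ValueError(f"Ct value {ct} outside (0, {CT_MAX}]")
    return ct


def delta_ct(ct_table: pd.DataFrame) -> list[ExpressionResult]:
    """Per-sample relative expression from a tidy Ct table.

    The table needs columns (sample, gene, replicate, ct) with gene in
    {"target", "reference"}, at least 3 replicates per gene per sample,
    and ct either numeric (0, 45] or the sentinel "UD".
    """
    required = {"sample", "gene", "replicate", "ct"}
    if not required.issubset(ct_table.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    results: list[ExpressionResult] = []
    for sample, grp in ct_table.groupby("sample", sort=True):
        target = grp[grp.gene == "target"].set_index("replicate")["ct"]
        reference = grp[grp.gene == "reference"].set_index("replicate")["ct"]
        if len(target) < 3 or len(reference) < 3:
            raise ValueError(f"{sample}: need >= 3 replicates for both genes")
        if any(str(v) == UNDETECTED for v in reference):
            results.append(ExpressionResult(str(sample), float("nan"), float("nan"),
                                            len(target), False, error="reference-failure"))
            continue
        n_ud = sum(str(v) == UNDETECTED for v in target)
        if n_ud * 2 >= len(target):
            results.append(ExpressionResult(str(sample), 0.0, 0.0, len(target), detected=False))
            continue
        expr = []
        for rep in target.index:
            if str(target[rep]) == UNDETECTED:
                continue  # minority dropout: drop the replicate
            if rep not in reference.index:
                raise ValueError(f"{sample}: replicate {rep} missing for the reference gene")
            dct = _validate_ct(target[rep]) - _validate_ct(reference[rep])
            expr.append(2.0 ** (-dct))
        arr = np.asarray(expr)
        results.append(
            ExpressionResult(str(sample), float(arr.mean()),
                             float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                             len(arr), detected=True)
        )
    return results


def expression_frame(results: list[ExpressionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [r.sample for r in results],
            "expression_mean": [r.expression_mean for r in results],
            "expression_sd": [r.expression_sd for r in results],
            "n_replicates": [r.n_replicates for r in results],
            "detected": [r.detected for r in results],
            "error": [r.error or "" for r in results],
        }
    )


def call_transcribed_region(
    coverage: np.ndarray, min_cov: int = 5, max_zero_run: int = 20
) -> list[tuple[int, int]]:
    """Transcribed intervals from a per-base coverage track.

    Maximal runs with coverage >= ``min_cov`` are reported 1-based
    inclusive; runs separated by sub-threshold gaps of at most
    ``max_zero_run`` bp merge into one interval. An empty list means
    nothing is expressed.
    """
    coverage = np.asarray(coverage)
    if coverage.ndim != 1 or len(coverage) == 0:
        raise ValueError("coverage must be a non-empty 1-D array")
    above = coverage >= min_cov
    if not above.any():
        return []
    # run-length encode the boolean track
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = [0] if above[0] else []
    starts += [int(e) + 1 for e in edges if not above[e]]
    ends = [int(e) for e in edges if above[e]]
    if above[-1]:
        ends.append(len(coverage) - 1)
    runs = list(zip(starts, ends))  # 0-based inclusive
    merged: list[list[int]] = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] - 1 <= max_zero_run:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s + 1, e + 1) for s, e in merged]
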