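"""Relative qPCR quantification by the 2^-ddCt method.

Each sample's target Ct is normalized to an internal reference gene
(dCt = Ct_target - Ct_reference), then to the baseline group
(ddCt = dCt - mean dCt of baseline), giving fold = 2^-ddCt. In paired
mode the two sides of each animal (e.g. crushed vs uncrushed nerve) are
ratioed within the animal before any group summary. Every fold is
invariant under a constant shift applied to all Ct values.
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["sample", "group", "pair", "gene", "ct"]


def _validate(records: pd.DataFrame, reference_gene: str) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if (records["ct"] <= 0).any():
        raise ValueError("Ct values must be > 0")
    wide = records.pivot_table(
        index=["sample", "group", "pair"], columns="gene", values="ct", aggfunc="mean"
    )
    if reference_gene not in wide.columns:
        raise ValueError(f"reference gene {reference_gene!r} absent from table")
    no_ref = wide.index[wide[reference_gene].isna()].tolist()
    if no_ref:
        raise ValueError(f"samples missing reference gene Ct: {no_ref}")
    return wide


@dataclass
class QpcrResult:
    folds: pd.DataFrame       # per sample (or per animal in paired mode)
    summary: pd.DataFrame     # per gene (and group): mean fold, t statistic, p


def delta_delta_ct(
    records: pd.DataFrame,
    reference_gene: str,
    baseline_group: str,
    paired: bool = False,
) -> QpcrResult:
    """Fold changes per sample/group from a long Ct table.

    ``records`` columns: sample, group, pair, gene, ct. All genes other
    than the reference are treated as targets. Unpaired mode compares each
    group's log2 folds against the baseline group by a two-tailed Student's
    t-test. Paired mode treats ``group`` as the side label, computes the
    per-animal fold ratio (other side / baseline side), and tests the log2
    ratios against zero with a one-sample t-test.
    """
    wide = _validate(records, reference_gene)
    targets = [g for g in wide.columns if g != reference_gene]
    if not targets:
        raise ValueError("no target genes in table")
    dct = wide[targets].sub(wide[reference_gene], axis=0)
    dct = dct.reset_index()

    if not paired:
        base = dct[dct["group"] == baseline_group]
        if base.empty:
            raise ValueError(f"baseline group {baseline_group!r} absent")
        rows = []
        for gene in targets:
            base_mean = base[gene].mean()
            for r in dct.itertuples():
                fold = 2.0 ** -(getattr(r, gene) - base_mean)
                rows.append((r.sample, r.group, gene, fold))
        folds = pd.DataFrame(rows, columns=["sample", "group", "gene", "fold"])
        summary_rows = []
        for gene in targets:
            gf = folds[folds["gene"] == gene]
            base_logs = np.log2(gf[gf["group"] == baseline_group]["fold"])
            for grp in gf["group"].unique():
                logs = np.log2(gf[gf["group"] == grp]["fold"])
                if grp == baseline_group:
                    t, p = 0.0, 1.0
                else:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        t, p = stats.ttest_ind(logs, base_logs)
                    if np.isnan(p):
                        t, p = 0.0, 1.0
                summary_rows.append((gene, grp, float(np.mean(gf[gf["group"] == grp]["fold"])),
                                     float(t), float(p)))
        summary = pd.DataFrame(
            summary_rows, columns=["gene", "group", "mean_fold", "t", "p"]
        )
        return QpcrResult(folds=folds, summary=summary)

    # paired mode: group column holds the two sides; baseline_group = denominator
    sides = sorted(dct["group"].unique())
    if baseline_group not in sides or len(sides) != 2:
        raise ValueError("paired mode needs exactly two sides incl. the baseline side")
    other = next(s for s in sides if s != baseline_group)
    rows = []
    for pair_id, sub in dct.groupby("pair"):
        for gene in targets:
            side_vals = {r.group: getattr(r, gene) for r in sub.itertuples()}
            if set(side_vals) != set(sides):
                missing_side = next(s for s in sides if s not in side_vals)
                raise ValueError(f"animal {pair_id!r} missing side {missing_side!r}")
            ratio = 2.0 ** -(side_vals[other] - side_vals[baseline_group])
            rows.append((pair_id, gene, ratio))
    folds = pd.DataFrame(rows, columns=["pair", "gene", "fold"])
    summary_rows = []
    for gene in targets:
        logs = np.log2(folds[folds["gene"] == gene]["fold"])
        if np.allclose(logs, 0) or logs.std(ddof=1) == 0:
            t, p = (0.0, 1.0) if np.allclose(logs, 0) else (np.inf, 0.0)
        else:
            t, p = stats.ttest_1samp(logs, 0.0)
        summary_rows.append(
            (gene, f"{other}/{baseline_group}",
             float(np.mean(folds[folds["gene"] == gene]["fold"])), float(t), float(p))
        )
    summary = pd.DataFrame(summary_rows, columns=["gene", "group", "mean_fold", "t", "p"])
    return QpcrResult(folds=folds, summary=summary)
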