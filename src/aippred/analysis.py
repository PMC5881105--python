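"""Compositional and positional enrichment statistics between peptide classes.

Which residues and dipeptides distinguish anti-inflammatory peptides from
inactive ones? Each peptide contributes its own composition vector, and
every item (residue, dipeptide, or position/residue indicator) is compared
between classes with a two-sided Welch t-test on those per-peptide values.
No multiple-testing correction is applied by default (raw p <= alpha), with
Benjamini-Hochberg available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError
from .features import encode_dataset
from .seqio import AMINO_ACIDS, PeptideDataset


@dataclass
class EnrichmentReport:
    """Per-item enrichment table plus the fraction of significant items."""

    table: pd.DataFrame
    significant_fraction: float


def _welch_columns(pos_values: np.ndarray, neg_values: np.ndarray,
                   items: list[str], alpha: float,
                   bh_correct: bool) -> EnrichmentReport:
    mean_pos = pos_values.mean(axis=0)
    mean_neg = neg_values.mean(axis=0)
    zero_var = (pos_values.var(axis=0) == 0) & (neg_values.var(axis=0) == 0)
    # both classes constant: equal means -> no information (p = NaN, flagged);
    # different means -> perfect separation (p -> 0)
    no_var = zero_var & (mean_pos == mean_neg)
    separated = zero_var & (mean_pos != mean_neg)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(pos_values, neg_values, axis=0, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    p[separated] = 0.0
    p[no_var] = np.nan
    df = pd.DataFrame({
        "item": items,
        "mean_pos": mean_pos,
        "mean_neg": mean_neg,
        "diff": mean_pos - mean_neg,
        "p_value": p,
        "no_variance": no_var,
    })
    if bh_correct:
        mask = ~df["p_value"].isna()
        padj = np.full(len(df), np.nan)
        padj[mask.to_numpy()] = stats.false_discovery_control(
            df.loc[mask, "p_value"].to_numpy())
        df["p_adjusted"] = padj
        df["significant"] = df["p_adjusted"] <= alpha
    else:
        df["significant"] = df["p_value"] <= alpha
    df = df.sort_values(["p_value", "item"], na_position="last",
                        kind="mergesort").reset_index(drop=True)
    tested = int((~df["p_value"].isna()).sum())
    frac = float(df["significant"].sum() / tested) if tested else float("nan")
    return EnrichmentReport(table=df, significant_fraction=frac)


def composition_enrichment(
    pos: PeptideDataset, neg: PeptideDataset, level: str = "aac",
    alpha: float = 0.05, bh_correct: bool = False,
) -> EnrichmentReport:
    """Welch t-test per residue (``aac``) or dipeptide (``dpc``) composition.

    Items where both classes have zero variance are flagged ``no_variance``
    with p = NaN rather than raising. Results sort by ascending p.
    """
    if level not in ("aac", "dpc"):
        raise ParameterError(f"level must be 'aac' or 'dpc', got {level!r}")
    if len(pos) < 2 or len(neg) < 2:
        raise ParameterError("each class needs >= 2 peptides (variance undefined)")
    pm = encode_dataset(pos, level)
    nm = encode_dataset(neg, level)
    items = [name.split("_", 1)[1] for name in pm.feature_names]
    return _welch_columns(pm.values, nm.values, items, alpha, bh_correct)


def _position_indicators(dataset: PeptideDataset, terminus: str,
                         n_positions: int) -> dict[int, np.ndarray]:
    # Per position (1-based from the chosen terminus), a peptides x 20
    # residue indicator matrix over the peptides long enough to have that
    # position. C-terminal position k is the k-th residue from the end.
    out: dict[int, np.ndarray] = {}
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for k in range(1, n_positions + 1):
        rows = []
        for rec in dataset:
            if len(rec) < k:
                continue
            ch = rec.sequence[k - 1] if terminus == "N" else rec.sequence[-k]
            row = np.zeros(20)
            row[aa_index[ch]] = 1.0
            rows.append(row)
        if rows:
            out[k] = np.vstack(rows)
    return out


def positional_enrichment(
    pos: PeptideDataset, neg: PeptideDataset, terminus: str = "N",
    n_positions: int = 10, alpha: float = 0.05, bh_correct: bool = False,
) -> EnrichmentReport:
    """Per (position, residue) indicator comparison between classes.

    Positions are counted 1..n from the N terminus inward, or for
    ``terminus="C"`` from the last residue inward. Peptides shorter than a
    position simply do not contribute to it; positions beyond every peptide
    yield no rows.
    """
    if terminus not in ("N", "C"):
        raise ParameterError("terminus must be 'N' or 'C'")
    if len(pos) == 0 or len(neg) == 0:
        raise ParameterError("both classes must be non-empty")
    pos_ind = _position_indicators(pos, terminus, n_positions)
    neg_ind = _position_indicators(neg, terminus, n_positions)
    frames, fracs_n, fracs_k = [], 0, 0
    for k in sorted(set(pos_ind) & set(neg_ind)):
        items = [f"{terminus}{k}:{aa}" for aa in AMINO_ACIDS]
        rep = _welch_columns(pos_ind[k], neg_ind[k], items, alpha, bh_correct)
        frames.append(rep.table)
        tested = int((~rep.table["p_value"].isna()).sum())
        fracs_n += int(rep.table["significant"].sum())
        fracs_k += tested
    if not frames:
        return EnrichmentReport(
            table=pd.DataFrame(columns=["item", "mean_pos", "mean_neg", "diff",
                                        "p_value", "no_variance", "significant"]),
            significant_fraction=float("nan"),
        )
    table = pd.concat(frames, ignore_index=True)
    table = table.sort_values(["p_value", "item"], na_position="last",
                              kind="mergesort").reset_index(drop=True)
    frac = fracs_n / fracs_k if fracs_k else float("nan")
    return EnrichmentReport(table=table, significant_fraction=frac)
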