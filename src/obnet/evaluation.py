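"""ROC comparison of disease rankings against a gold trait list.

A ranking method produces one score per disease (an adjusted p-value, a
mean distance, or a Jaccard coefficient); gold-list membership is the
positive label.  The ROC treats the ranking score as the decision
statistic and the area under the curve summarises how well the method
separates gold from non-gold diseases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(
    ranking: pd.DataFrame,
    gold,
    score_col: str | None = None,
    ascending: bool = True,
    missing: str = "worst",
    blocklist=(),
    universe=None,
) -> RocCurve:
    """ROC/AUC of a disease ranking against a gold list.

    Parameters
    ----------
    ranking
        DataFrame with a ``disease_id`` column and one score column
        (auto-detected when ``score_col`` is None and the frame has
        exactly one other numeric column).
    ascending
        True when a smaller score means "more positive" (p-values,
        distances); False for similarity scores (Jaccard).
    missing
        Gold diseases absent from the ranking are appended at the worst
        possible score (``'worst'``, default) or ignored (``'drop'``).
        The choice moves the AUC and is therefore explicit.
    universe
        Optional full disease catalogue: with ``missing='worst'`` every
        catalogue disease absent from the ranking — gold or not — is
        appended at the worst score ("could not be scored" reads as "no
        evidence of association").  Keeps comparisons fair between methods
        whose eligibility filters drop different diseases.
    blocklist
        Disease ids excluded from evaluation (e.g. self-referential traits
        of the query itself).

    Ties contribute 0.5 per tied positive-negative pair (the rank-sum
    convention).
    """
    if score_col is None:
        numeric = [c for c in ranking.columns if c != "disease_id" and pd.api.types.is_numeric_dtype(ranking[c])]
        if len(numeric) != 1:
            raise ValueError(f"cannot auto-detect score column among {numeric}")
        score_col = numeric[0]
    gold = frozenset(gold)
    blocklist = frozenset(blocklist)
    df = ranking[~ranking["disease_id"].isin(blocklist)][["disease_id", score_col]].copy()
    ranked_ids = set(df["disease_id"])
    if missing == "worst":
        pool = frozenset(universe) | gold if universe is not None else gold
        absent = sorted(g for g in pool - ranked_ids if g not in blocklist)
        if absent:
            worst = np.inf if ascending else -np.inf
            df = pd.concat(
                [df, pd.DataFrame({"disease_id": absent, score_col: worst})],
                ignore_index=True,
            )
    elif missing != "drop":
        raise ValueError(f"unknown missing policy {missing!r}")
    labels = df["disease_id"].isin(gold).to_numpy(dtype=int)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("ROC needs both gold and non-gold diseases in the ranking")
    scores = df[score_col].to_numpy(dtype=float)
    decision = -scores if ascending else scores
    # replace infinities so sklearn's threshold sweep stays finite
    finite = decision[np.isfinite(decision)]
    lo = finite.min() - 1.0 if finite.size else -1.0
    decision = np.where(np.isneginf(decision), lo, decision)
    fpr, tpr, thr = roc_curve(labels, decision)
    auc = float(roc_auc_score(labels, decision))
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)
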