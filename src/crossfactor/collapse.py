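"""Collapse probeset-level category calls to gene-level calls.

Arrays interrogate many genes with several probesets; downstream enrichment
wants one call per gene.  The rule is conservative: a gene is retained only
if every one of its probesets received the same category label, otherwise it
is dropped with reason ``pattern-conflict``.  The retained gene inherits the
call of its representative probeset — the one with the highest mean
intensity across all samples, a deterministic and conventional choice.

Probesets absent from the map pass through as singleton pseudo-genes and are
flagged ``unmapped`` so they can be excluded from annotation-based tests.
"""

from __future__ import annotations

import pandas as pd

from .io import GeneMap

__all__ = ["collapse"]


def collapse(
    calls: pd.DataFrame,
    gene_map: GeneMap,
    mean_intensity: pd.Series | None = None,
    on: tuple[str, ...] = ("category",),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse probeset calls to gene calls, dropping discordant genes.

    Parameters
    ----------
    calls
        classify() output; must contain ``probeset_id`` and the columns in
        *on*.
    gene_map
        probeset -> gene mapping (many-to-one).
    mean_intensity
        per-probeset mean intensity used to pick the representative
        probeset; when omitted, the first probeset in call order represents
        the gene.
    on
        columns that must agree across a gene's probesets for the gene to be
        retained (category by default; add ``direction_factor1`` etc. for a
        stricter pattern definition).

    Returns
    -------
    (gene_calls, dropped) DataFrames.
    """
    if len(gene_map) == 0:
        raise ValueError("empty gene map")
    for col in ("probeset_id", *on):
        if col not in calls.columns:
            raise ValueError(f"calls table lacks column {col!r}")

    work = calls.copy()
    work["gene_id"] = [
        gene_map.gene_of(ps) if gene_map.gene_of(ps) is not None else ps
        for ps in work["probeset_id"]
    ]
    work["unmapped"] = [gene_map.gene_of(ps) is None for ps in work["probeset_id"]]
    if mean_intensity is not None:
        work["_intensity"] = mean_intensity.reindex(work["probeset_id"]).to_numpy()
    else:
        work["_intensity"] = 0.0

    retained_rows = []
    dropped_rows = []
    for gene_id, grp in work.groupby("gene_id", sort=True):
        patterns = grp[list(on)].drop_duplicates()
        if len(patterns) > 1:
            labels = sorted(
                "/".join(str(v) for v in row) for row in grp[list(on)].to_numpy()
            )
            dropped_rows.append(
                {
                    "gene_id": gene_id,
                    "n_probesets": len(grp),
                    "reason": "pattern-conflict",
                    "conflicting_labels": ",".join(sorted(set(labels))),
                }
            )
            continue
        rep = grp.loc[grp["_intensity"].idxmax()]
        retained_rows.append(
            {
                "gene_id": gene_id,
                "category": rep["category"],
                "representative_probeset": rep["probeset_id"],
                "n_probesets": len(grp),
                "unmapped": bool(rep["unmapped"]),
                **{
                    col: rep[col]
                    for col in calls.columns
                    if col not in ("probeset_id", "category")
                },
            }
        )
    gene_calls = pd.DataFrame(
        retained_rows,
        columns=["gene_id", "category", "representative_probeset", "n_probesets", "unmapped"]
        + [c for c in calls.columns if c not in ("probeset_id", "category")],
    )
    dropped = pd.DataFrame(
        dropped_rows, columns=["gene_id", "n_probesets", "reason", "conflicting_labels"]
    )
    return gene_calls, dropped
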