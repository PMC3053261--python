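"""Synthetic 2x2 factorial expression experiments with known ground truth.

The generator emulates a knock-down x stimulus microarray study: each gene
gets a latent response category (A factor-1 only, B factor-2 only, C
additive, D interactive, or none), log2-scale effect sizes consistent with
that category, and one to three probesets sharing the gene's effects.  For
design cell (i, j) and replicate noise eps ~ Normal(0, sigma^2),

    log2 value = baseline + i*beta1 + j*beta2 + i*j*beta12 + eps,

and the emitted matrix is linear scale (2**log2), i.e. log-normal
intensities — the standard multiplicative microarray error model.

Interactive (D) genes follow one of eight archetype shapes covering the
qualitatively distinct 2x2 interaction profiles; two focal archetypes —
"up only under the combined treatment" and "down only under knock-down
alone" — preferentially receive genes of a planted inflammatory-response
set, so set-in-cluster enrichment is a recoverable signal.  Companion
generators plant a consensus motif into responsive-gene promoters at an
elevated rate and draw an external "bound gene" list with a configurable
odds ratio favoring factor-1-responsive genes.

All randomness flows from a single master seed through named substreams, so
identical configurations give byte-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import PFM, ExpressionBundle, GeneMap, GeneSetCollection, PromoterSet

__all__ = [
    "SimConfig",
    "D_ARCHETYPES",
    "FOCAL_ARCHETYPES",
    "ELK1_LIKE_PFM",
    "simulate_expression",
    "simulate_promoters",
    "simulate_bound_list",
    "simulate_gene_sets",
    "write_bundle",
]

#: Interaction archetypes as 4-vectors of unit cell effects in the order
#: (control, factor2, factor1, both); each implies a nonzero interaction.
D_ARCHETYPES = {
    1: (0.0, 0.0, -1.0, 0.0),   # down under knock-down alone, restored by stimulus
    2: (0.0, 0.0, 0.0, 1.0),    # up only under the combined treatment
    3: (0.0, 0.0, 1.0, 0.0),    # up under knock-down alone
    4: (0.0, 0.0, 0.0, -1.0),   # down only under the combined treatment
    5: (0.0, 1.0, 1.0, 0.0),    # each alone up, combination cancels
    6: (0.0, -1.0, -1.0, 0.0),  # each alone down, combination cancels
    7: (0.0, 0.0, 1.0, 2.0),    # knock-down up, amplified by stimulus
    8: (0.0, 0.0, -1.0, -2.0),  # knock-down down, amplified by stimulus
}

#: archetypes that receive planted inflammatory-set genes
FOCAL_ARCHETYPES = (2, 1)

#: Sharp ETS-like planted motif; consensus CCGGAAG with a G/A split in the
#: final position.
ELK1_LIKE_PFM = PFM(
    name="ELK1_like",
    counts=np.array(
        [
            # C   C   G   G   A   A   G/A
            [0,   0,  0,  0, 18, 18,  6],   # A
            [18, 18,  0,  0,  0,  0,  0],   # C
            [0,   0, 18, 18,  0,  0, 12],   # G
            [0,   0,  0,  0,  0,  0,  0],   # T
        ]
    ),
)


@dataclass
class SimConfig:
    """All knobs of the synthetic experiment.

    Effect sizes are |log2 fold changes| drawn uniformly from
    ``effect_range`` with random sign (archetypes fix the sign pattern for
    interactive genes); ``sigma`` is the replicate noise sd on the log2
    scale.  Category proportions echo the scale of a genome-wide knock-down
    experiment in which roughly 40% of probesets respond.
    """

    n_genes: int = 14220
    replicates: int = 4
    category_proportions: dict = field(
        default_factory=lambda: {"A": 0.25, "B": 0.04, "C": 0.07, "D": 0.04}
    )
    effect_range: tuple[float, float] = (2.0, 3.0)
    sigma: float = 0.25
    baseline_range: tuple[float, float] = (6.0, 12.0)
    multi_probeset_frac: float = 0.10
    # gene-set planting
    n_inflammatory: int = 170
    inflam_route_frac: float = 0.3
    n_metabolic: int = 3000
    metabolic_odds: float = 2.0
    # external bound list
    bound_size: int = 1219
    bound_odds: float = 3.0
    # promoters and motifs
    promoter_length: int = 1500
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    p_motif_responsive: float = 0.4
    p_motif_background: float = 0.1
    n_decoy_motifs: int = 10
    seed: int = 17
    require_null_genes: bool = False

    def __post_init__(self) -> None:
        total = sum(self.category_proportions.values())
        if total > 1 + 1e-9:
            raise ValueError("category proportions must sum to <= 1")
        unknown = set(self.category_proportions) - {"A", "B", "C", "D"}
        if unknown:
            raise ValueError(f"unknown categories in proportions: {sorted(unknown)}")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per cell")
        if not 0 <= self.multi_probeset_frac <= 1:
            raise ValueError("multi_probeset_frac must be in [0, 1]")
        bc = np.asarray(self.base_composition, dtype=float)
        if bc.shape != (4,) or (bc <= 0).any():
            raise ValueError("base_composition must be 4 positive frequencies")

    def rng(self, stream: str) -> np.random.Generator:
        """Named deterministic substream of the master seed."""
        root = np.random.SeedSequence(self.seed)
        salt = int.from_bytes(stream.encode(), "big") % (2**31)
        return np.random.default_rng(np.random.SeedSequence(entropy=(self.seed, salt)))


def _assign_categories(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    props = config.category_proportions
    cats = ["A", "B", "C", "D", "none"]
    p_none = max(0.0, 1.0 - sum(props.values()))
    p = [props.get(c, 0.0) for c in "ABCD"] + [p_none]
    return rng.choice(cats, size=config.n_genes, p=np.array(p) / sum(p))


def simulate_expression(
    config: SimConfig,
) -> tuple[ExpressionBundle, GeneMap, pd.DataFrame]:
    """Generate the expression bundle, probeset->gene map and truth table.

    The truth table is indexed by gene id with columns ``category``,
    ``beta_factor1``, ``beta_factor2``, ``beta_interaction`` (log2 scale),
    ``archetype`` (0 for non-D genes), and planted-membership flags
    ``inflammatory`` and ``metabolic`` (``bound`` and ``motif_planted`` are
    filled in by the companion generators).
    """
    rng = config.rng("expression")
    n = config.n_genes
    genes = np.array([f"g{i:05d}" for i in range(n)])
    category = _assign_categories(config, rng)

    # route a fraction of the inflammatory set into the focal D archetypes
    n_inflam = min(config.n_inflammatory, n)
    n_route = int(round(config.inflam_route_frac * n_inflam))
    routed = rng.choice(n, size=n_route, replace=False) if n_route else np.array([], int)
    archetype = np.zeros(n, dtype=int)
    is_d = category == "D"
    archetype[is_d] = rng.integers(1, 9, size=int(is_d.sum()))
    for pos, gi in enumerate(routed):
        category[gi] = "D"
        archetype[gi] = FOCAL_ARCHETYPES[pos % len(FOCAL_ARCHETYPES)]

    if config.require_null_genes and not (category == "none").any():
        raise ValueError(
            "no null-category genes in the design; calibration tests need some"
        )

    lo, hi = config.effect_range
    size = rng.uniform(lo, hi, size=n)
    sign1 = rng.choice([-1.0, 1.0], size=n)
    sign2 = rng.choice([-1.0, 1.0], size=n)
    beta1 = np.zeros(n)
    beta2 = np.zeros(n)
    beta12 = np.zeros(n)
    for ci, cat in enumerate(category):
        if cat == "A":
            beta1[ci] = sign1[ci] * size[ci]
        elif cat == "B":
            beta2[ci] = sign2[ci] * size[ci]
        elif cat == "C":
            beta1[ci] = sign1[ci] * size[ci]
            beta2[ci] = sign2[ci] * rng.uniform(lo, hi)
        elif cat == "D":
            t = np.array(D_ARCHETYPES[archetype[ci]])
            # cell-mean template (ctrl, f2, f1, both) -> factorial effects
            s = size[ci]
            beta2[ci] = t[1] * s
            beta1[ci] = t[2] * s
            beta12[ci] = (t[3] - t[1] - t[2]) * s

    # a gene with no effect at all is truly null whatever label it drew
    # (degenerate when the effect range collapses to zero)
    null_effect = (beta1 == 0) & (beta2 == 0) & (beta12 == 0)
    category[null_effect] = "none"
    archetype[null_effect] = 0

    # inflammatory set = routed genes + uniform draws from the rest
    inflam = np.zeros(n, dtype=bool)
    inflam[routed] = True
    remaining = np.setdiff1d(np.arange(n), routed)
    n_more = n_inflam - n_route
    if n_more > 0 and remaining.size:
        inflam[rng.choice(remaining, size=min(n_more, remaining.size), replace=False)] = True

    # metabolic set leans toward factor-1-responsive genes
    metabolic = np.zeros(n, dtype=bool)
    n_met = min(config.n_metabolic, n)
    if n_met:
        f1_resp = np.isin(category, ["A", "C", "D"])
        w = np.where(f1_resp, config.metabolic_odds, 1.0)
        metabolic[rng.choice(n, size=n_met, replace=False, p=w / w.sum())] = True

    # probesets: ~multi_probeset_frac of genes carry 2-3 probesets
    extra = np.zeros(n, dtype=int)
    multi = rng.random(n) < config.multi_probeset_frac
    extra[multi] = rng.integers(1, 3, size=int(multi.sum()))
    probe_gene_idx = np.repeat(np.arange(n), 1 + extra)
    probeset_ids = []
    counters = np.zeros(n, dtype=int)
    for gi in probe_gene_idx:
        counters[gi] += 1
        probeset_ids.append(f"{genes[gi]}_ps{counters[gi]}")
    probeset_ids = np.array(probeset_ids)

    baseline = rng.uniform(*config.baseline_range, size=n)
    r = config.replicates
    design_rows = []
    sample_ids = []
    cells = [("control", "control"), ("control", "treated"),
             ("treated", "control"), ("treated", "treated")]
    for ci, (f1, f2) in enumerate(cells):
        for rep in range(1, r + 1):
            sid = f"s{ci * r + rep:02d}"
            sample_ids.append(sid)
            design_rows.append({"sample_id": sid, "factor1": f1, "factor2": f2,
                                "replicate": rep})
    design = pd.DataFrame(design_rows).set_index("sample_id")

    i_lev = np.array([0, 0, 1, 1])
    j_lev = np.array([0, 1, 0, 1])
    n_ps = len(probe_gene_idx)
    log2_means = (
        baseline[probe_gene_idx][:, None]
        + np.outer(beta1[probe_gene_idx], i_lev)
        + np.outer(beta2[probe_gene_idx], j_lev)
        + np.outer(beta12[probe_gene_idx], i_lev * j_lev)
    )  # n_ps x 4 cells
    noise = rng.normal(0.0, config.sigma, size=(n_ps, 4, r))
    log2_values = log2_means[:, :, None] + noise
    values = pd.DataFrame(
        2.0 ** log2_values.reshape(n_ps, 4 * r),
        index=probeset_ids,
        columns=sample_ids,
    )
    bundle = ExpressionBundle(values=values, design=design)
    gene_map = GeneMap(mapping=dict(zip(probeset_ids, genes[probe_gene_idx])))
    truth = pd.DataFrame(
        {
            "category": category,
            "beta_factor1": beta1,
            "beta_factor2": beta2,
            "beta_interaction": beta12,
            "archetype": archetype,
            "inflammatory": inflam,
            "metabolic": metabolic,
            "bound": False,
            "motif_planted": False,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return bundle, gene_map, truth


def _random_decoy(rng: np.random.Generator, idx: int) -> PFM:
    """A sharp random-consensus decoy motif of length 9-11, never planted.

    Consensi containing the planted ETS core (or its reverse complement)
    are redrawn so decoy presence stays independent of motif planting.
    """
    while True:
        L = int(rng.integers(9, 12))
        cons = rng.integers(0, 4, size=L)
        word = "".join("ACGT"[b] for b in cons)
        if "CCGGAA" not in word and "TTCCGG" not in word:
            break
    counts = np.zeros((4, L))
    counts[cons, np.arange(L)] = 18.0
    return PFM(name=f"decoy{idx:02d}", counts=counts)


def simulate_promoters(
    config: SimConfig, truth: pd.DataFrame
) -> tuple[PromoterSet, list[PFM]]:
    """Generate promoters with the planted motif and a decoy PFM library.

    Background sequence is i.i.d. at ``base_composition``; a motif instance
    (sampled from the planted PFM's column frequencies) is inserted at a
    random offset with probability ``p_motif_responsive`` for factor-1
    responsive genes and ``p_motif_background`` otherwise.
    """
    rng = config.rng("promoters")
    planted = ELK1_LIKE_PFM
    if planted.length > config.promoter_length:
        raise ValueError("motif longer than promoter")
    bases = np.array(list("ACGT"))
    bc = np.asarray(config.base_composition, dtype=float)
    bc = bc / bc.sum()
    genes = list(truth.index)
    responsive = truth["category"].isin(["A", "C", "D"]).to_numpy()
    seqs = rng.choice(4, size=(len(genes), config.promoter_length), p=bc)
    col_probs = planted.counts / planted.counts.sum(axis=0)
    plant_p = np.where(responsive, config.p_motif_responsive, config.p_motif_background)
    do_plant = rng.random(len(genes)) < plant_p
    offsets = rng.integers(0, config.promoter_length - planted.length + 1,
                           size=len(genes))
    for gi in np.nonzero(do_plant)[0]:
        inst = np.array(
            [rng.choice(4, p=col_probs[:, j]) for j in range(planted.length)]
        )
        seqs[gi, offsets[gi] : offsets[gi] + planted.length] = inst
    sequences = {g: "".join(bases[row]) for g, row in zip(genes, seqs)}
    truth["motif_planted"] = do_plant
    decoy_rng = config.rng("decoys")
    pfms = [planted] + [_random_decoy(decoy_rng, i + 1) for i in range(config.n_decoy_motifs)]
    return (
        PromoterSet(
            sequences=sequences,
            metadata={"window": "synthetic", "length": config.promoter_length},
        ),
        pfms,
    )


def simulate_bound_list(config: SimConfig, truth: pd.DataFrame) -> list[str]:
    """Draw the external bound-gene list with enrichment for factor-1
    responsive genes at odds ``bound_odds``; size 0 gives an empty list."""
    if config.bound_size > len(truth):
        raise ValueError(
            f"bound list size {config.bound_size} exceeds gene count {len(truth)}"
        )
    if config.bound_size == 0:
        return []
    rng = config.rng("bound")
    responsive = truth["category"].isin(["A", "C", "D"]).to_numpy()
    w = np.where(responsive, config.bound_odds, 1.0)
    idx = rng.choice(len(truth), size=config.bound_size, replace=False, p=w / w.sum())
    truth["bound"] = False
    truth.iloc[idx, truth.columns.get_loc("bound")] = True
    return sorted(truth.index[idx])


def simulate_gene_sets(
    config: SimConfig, truth: pd.DataFrame, n_top_level: int = 26
) -> GeneSetCollection:
    """Gene-set collection holding the planted inflammatory and metabolic
    sets plus random filler sets, all flagged top-level to mirror a broad
    process scan of *n_top_level* families."""
    rng = config.rng("genesets")
    genes = np.array(truth.index)
    sets = {
        name: members
        for name, members in (
            ("inflammatory_response", frozenset(truth.index[truth["inflammatory"]])),
            ("metabolic_process", frozenset(truth.index[truth["metabolic"]])),
        )
        if members
    }
    n_filler = max(0, n_top_level - len(sets))
    for i in range(n_filler):
        size = int(rng.integers(50, max(51, len(genes) // 10)))
        size = min(size, len(genes))
        members = rng.choice(genes, size=size, replace=False)
        sets[f"process_{i + 1:02d}"] = frozenset(members)
    return GeneSetCollection(sets=sets, top_level=frozenset(sets))


def _pfm_to_jaspar(pfms: list[PFM]) -> str:
    lines = []
    for pfm in pfms:
        lines.append(f">{pfm.name}")
        for base, row in zip("ACGT", pfm.counts):
            lines.append(
                f"{base}  [ " + "  ".join(str(int(x)) for x in row) + " ]"
            )
    return "\n".join(lines) + "\n"


def write_bundle(config: SimConfig, out_dir) -> Path:
    """Generate a full input bundle and write it as plain-text files.

    Emits matrix.tsv, samples.tsv, gene_map.tsv, genesets.gmt,
    promoters.fasta, motifs.pfm, bound_genes.txt, truth.tsv and config.yaml.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle, gene_map, truth = simulate_expression(config)
    promoters, pfms = simulate_promoters(config, truth)
    bound = simulate_bound_list(config, truth)
    genesets = simulate_gene_sets(config, truth)

    bundle.values.rename_axis("probeset_id").to_csv(out / "matrix.tsv", sep="\t")
    bundle.design.reset_index().to_csv(out / "samples.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"probeset_id": list(gene_map.mapping), "gene_id": list(gene_map.mapping.values())}
    ).to_csv(out / "gene_map.tsv", sep="\t", index=False)
    with open(out / "genesets.gmt", "w") as fh:
        for name, members in genesets.sets.items():
            fh.write("\t".join([name, "top_level"] + sorted(members)) + "\n")
    with open(out / "promoters.fasta", "w") as fh:
        for gid, seq in promoters.sequences.items():
            fh.write(f">{gid}\n")
            for k in range(0, len(seq), 80):
                fh.write(seq[k : k + 80] + "\n")
    (out / "motifs.pfm").write_text(_pfm_to_jaspar(pfms))
    (out / "bound_genes.txt").write_text("\n".join(bound) + ("\n" if bound else ""))
    truth.reset_index().to_csv(out / "truth.tsv", sep="\t", index=False)
    cfg = asdict(config)
    cfg["effect_range"] = list(config.effect_range)
    cfg["baseline_range"] = list(config.baseline_range)
    cfg["base_composition"] = list(config.base_composition)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    return out
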