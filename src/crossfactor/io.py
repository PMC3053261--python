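"""Readers and writers for every external artifact the pipeline touches.

All formats are plain text: TSV expression matrix + sample sheet, GMT gene
sets, FASTA promoters, JASPAR raw-count position frequency matrices, and
one-gene-per-line lists.  Every reader validates its input and raises
:class:`FormatError` with enough context (line numbers, offending ids) to fix
the file by hand.
"""

from __future__ import annotations

import hashlib
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "ExpressionBundle",
    "GeneMap",
    "GeneSetCollection",
    "PromoterSet",
    "PFM",
    "read_expression",
    "read_gene_map",
    "read_gene_list",
    "read_gmt",
    "read_jaspar_pfm",
    "read_fasta_promoters",
    "write_results",
    "read_results_table",
]

FACTOR_LEVELS = ("control", "treated")

#: canonical display order of the four design cells:
#: (factor1, factor2) = (control, control), (control, treated),
#: (treated, control), (treated, treated)
CELL_ORDER = [
    ("control", "control"),
    ("control", "treated"),
    ("treated", "control"),
    ("treated", "treated"),
]


class FormatError(ValueError):
    """Malformed or internally inconsistent input artifact."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionBundle:
    """Linear-scale expression matrix plus its 2x2 factorial design.

    Parameters
    ----------
    values
        probesets x samples matrix of nonnegative linear-scale intensities
        (as produced by array summarization, e.g. MAS 5.0).
    design
        one row per sample, indexed by sample id, with columns
        ``factor1``, ``factor2`` (each ``control`` or ``treated``) and
        ``replicate`` (integer >= 1).
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        v, d = self.values, self.design
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise FormatError(f"duplicate probeset id: {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        if d.index.duplicated().any():
            dup = d.index[d.index.duplicated()][0]
            raise FormatError(f"duplicate sample id in design: {dup!r}")
        missing = [s for s in v.columns if s not in d.index]
        if missing:
            raise FormatError(f"samples absent from sample sheet: {missing}")
        extra = [s for s in d.index if s not in v.columns]
        if extra:
            raise FormatError(f"sheet samples absent from the matrix: {extra}")
        for col in ("factor1", "factor2"):
            bad = sorted(set(d[col]) - set(FACTOR_LEVELS))
            if bad:
                raise FormatError(f"{col} levels must be in {FACTOR_LEVELS}, got {bad}")
        for f1, f2 in CELL_ORDER:
            n = int(((d["factor1"] == f1) & (d["factor2"] == f2)).sum())
            if n < 2:
                raise FormatError(
                    f"design cell ({f1}, {f2}) has {n} replicate(s); need >= 2"
                )
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            coerced = v.apply(pd.to_numeric, errors="coerce")
            bad = coerced.isna() & v.notna()
            if bad.any().any():
                r, c = np.argwhere(bad.to_numpy())[0]
                raise FormatError(
                    f"non-numeric value {v.iat[r, c]!r} at probeset "
                    f"{v.index[r]!r}, sample {v.columns[c]!r}"
                )
            arr = coerced.to_numpy()
            self.values = coerced
        if not np.all(np.isfinite(arr)):
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                f"non-finite value at probeset {v.index[r]!r}, sample {v.columns[c]!r}"
            )
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative intensity at probeset {v.index[r]!r}, sample {v.columns[c]!r}"
            )
        # align design rows with matrix column order
        self.design = d.loc[list(v.columns)]

    @property
    def probeset_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def cell_samples(self) -> dict[tuple[str, str], list[str]]:
        """Sample ids of each design cell, keyed by (factor1, factor2)."""
        out: dict[tuple[str, str], list[str]] = {}
        for f1, f2 in CELL_ORDER:
            mask = (self.design["factor1"] == f1) & (self.design["factor2"] == f2)
            out[(f1, f2)] = list(self.design.index[mask])
        return out


@dataclass
class GeneMap:
    """Many-to-one probeset -> gene mapping."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        for ps, g in self.mapping.items():
            if not isinstance(g, str) or not g:
                raise FormatError(f"empty gene id for probeset {ps!r}")

    def __len__(self) -> int:
        return len(self.mapping)

    def gene_of(self, probeset: str) -> str | None:
        return self.mapping.get(probeset)

    def genes(self) -> set[str]:
        return set(self.mapping.values())


@dataclass
class GeneSetCollection:
    """Named gene sets, optionally flagging broad top-level process sets."""

    sets: dict[str, frozenset[str]]
    top_level: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
        unknown = self.top_level - set(self.sets)
        if unknown:
            raise FormatError(f"top-level flags for unknown sets: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def n_top_level(self) -> int:
        return len(self.top_level)

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        names = list(names)
        return GeneSetCollection(
            sets={n: self.sets[n] for n in names},
            top_level=self.top_level & set(names),
        )


@dataclass
class PromoterSet:
    """One uppercase promoter sequence (A/C/G/T/N) per gene id."""

    sequences: dict[str, str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gid, seq in self.sequences.items():
            bad = set(seq) - set("ACGTN")
            if bad:
                raise FormatError(
                    f"promoter {gid!r} contains non-ACGTN character(s): {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.sequences)

    def subset(self, gene_ids: Iterable[str]) -> "PromoterSet":
        gene_ids = list(gene_ids)
        missing = [g for g in gene_ids if g not in self.sequences]
        if missing:
            raise FormatError(f"no promoter for gene(s): {missing[:5]}")
        return PromoterSet(
            sequences={g: self.sequences[g] for g in gene_ids},
            metadata=dict(self.metadata),
        )


@dataclass
class PFM:
    """Position frequency matrix: 4 x L raw counts, rows ordered A, C, G, T."""

    name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise FormatError(f"PFM {self.name!r}: counts must be 4 x L")
        if self.counts.shape[1] < 4:
            raise FormatError(f"PFM {self.name!r}: motif length must be >= 4")
        if (self.counts < 0).any():
            raise FormatError(f"PFM {self.name!r}: negative count")
        if (self.counts.sum(axis=0) <= 0).any():
            raise FormatError(f"PFM {self.name!r}: column with zero total count")

    @property
    def length(self) -> int:
        return int(self.counts.shape[1])

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.counts, axis=0))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_expression(matrix_path, sample_sheet_path) -> ExpressionBundle:
    """Read a TSV expression matrix and its sample sheet into a validated bundle.

    The matrix has a header row of sample ids and probeset ids in the first
    column; the sheet has columns ``sample_id``, ``factor1``, ``factor2``,
    ``replicate``.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    sheet = pd.read_csv(sample_sheet_path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "factor1", "factor2", "replicate"}
    missing_cols = required - set(sheet.columns)
    if missing_cols:
        raise FormatError(f"sample sheet lacks column(s): {sorted(missing_cols)}")
    design = sheet.set_index("sample_id")[["factor1", "factor2", "replicate"]]
    design["replicate"] = design["replicate"].astype(int)
    if (design["replicate"] < 1).any():
        raise FormatError("replicate indices must be >= 1")
    return ExpressionBundle(values=values, design=design)


def read_gene_map(path) -> GeneMap:
    """Read a two-column TSV (probeset_id, gene_id)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("gene map needs two columns: probeset_id, gene_id")
    ps_col, gene_col = df.columns[:2]
    if df[ps_col].duplicated().any():
        dup = df[ps_col][df[ps_col].duplicated()].iloc[0]
        raise FormatError(f"probeset mapped twice: {dup!r}")
    return GeneMap(mapping=dict(zip(df[ps_col], df[gene_col])))


def read_gene_list(path) -> list[str]:
    """Read a one-gene-per-line list (e.g. an external ChIP bound-gene list)."""
    out: list[str] = []
    seen: set[str] = set()
    for line in Path(path).read_text().splitlines():
        gid = line.strip()
        if not gid or gid.startswith("#"):
            continue
        if gid not in seen:
            seen.add(gid)
            out.append(gid)
    return out


def read_gmt(path, top_level_marker: str = "top_level") -> GeneSetCollection:
    """Read GMT gene sets; sets whose description contains *top_level_marker*
    are flagged as broad top-level process sets.

    Duplicate members within a set are collapsed; empty sets and lines with
    fewer than three fields are rejected.
    """
    sets: dict[str, frozenset[str]] = {}
    top: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
        name, desc = fields[0], fields[1]
        members = frozenset(m for m in fields[2:] if m)
        if name in sets:
            raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
        if not members:
            raise FormatError(f"GMT line {lineno}: set {name!r} has no members")
        sets[name] = members
        if top_level_marker and top_level_marker in desc:
            top.add(name)
    return GeneSetCollection(sets=sets, top_level=frozenset(top))


def read_jaspar_pfm(path) -> list[PFM]:
    """Read JASPAR raw-count PFM text into a list of :class:`PFM`.

    Accepts both the bracketed dialect (``A  [ 8  0 ... ]``) and the plain
    whitespace dialect (four bare count rows in A, C, G, T order) under
    ``>name`` headers; semantically identical files parse to equal matrices.
    """
    text = Path(path).read_text()
    motifs: list[PFM] = []
    name: str | None = None
    rows: list[list[float]] = []
    row_letters: list[str | None] = []

    def flush() -> None:
        nonlocal rows, row_letters
        if name is None and not rows:
            return
        if len(rows) != 4:
            raise FormatError(f"PFM {name!r}: expected 4 count rows, got {len(rows)}")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise FormatError(f"PFM {name!r}: rows of unequal length {sorted(lengths)}")
        letters = [l for l in row_letters if l is not None]
        ordered = rows
        if letters:
            if sorted(letters) != ["A", "C", "G", "T"]:
                raise FormatError(f"PFM {name!r}: row labels must be A, C, G, T")
            order = {l: r for l, r in zip(row_letters, rows)}
            ordered = [order[b] for b in "ACGT"]
        motifs.append(PFM(name=name or f"motif{len(motifs) + 1}", counts=np.array(ordered)))
        rows, row_letters = [], []

    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            if rows:
                flush()
            name = line[1:].split()[0] if line[1:].split() else "unnamed"
            continue
        letter = None
        body = line
        head = line.split(None, 1)[0]
        if head.rstrip(":") in "ACGT" and len(head.rstrip(":")) == 1:
            letter = head.rstrip(":")
            body = line.split(None, 1)[1] if len(line.split(None, 1)) > 1 else ""
        body = body.replace("[", " ").replace("]", " ")
        try:
            counts = [float(tok) for tok in body.split()]
        except ValueError as exc:
            raise FormatError(f"PFM {name!r}: unparsable count row {raw!r}") from exc
        if any(c < 0 for c in counts):
            raise FormatError(f"PFM {name!r}: negative count in row {raw!r}")
        rows.append(counts)
        row_letters.append(letter)
    if rows or name is not None:
        flush()
    return motifs


def read_fasta_promoters(path, metadata: Mapping | None = None) -> PromoterSet:
    """Read promoter FASTA keyed by gene id; bases are upper-cased and
    restricted to A/C/G/T/N; duplicate headers are rejected."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"duplicate FASTA header: {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    return PromoterSet(sequences=sequences, metadata=dict(metadata or {}))


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping (order-independent)."""
    import json

    canon = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_results(
    tables: Mapping[str, pd.DataFrame], out_dir, metadata: Mapping | None = None
) -> list[Path]:
    """Write result tables as TSV with a ``#``-prefixed run-metadata header.

    Column order is preserved as given; metadata lines (seed, version, config
    hash, ...) precede the header row so the files round-trip through
    :func:`read_results_table`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, table in tables.items():
        path = out_dir / f"{name}.tsv"
        buf = _io.StringIO()
        for key, value in (metadata or {}).items():
            buf.write(f"# {key}: {value}\n")
        table.to_csv(buf, sep="\t", index=False)
        path.write_text(buf.getvalue())
        written.append(path)
    return written


def read_results_table(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_results` (skipping metadata)."""
    return pd.read_csv(path, sep="\t", comment="#")
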