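"""Readers and writers for the external formats the pipeline touches.

Formats
-------
- transcript count matrices: TSV, first column transcript ids, header = sample ids,
  integer cells (one file per species);
- sample metadata: TSV with columns sample_id, species_id, treatment (PBS|alum),
  fibrosis_score (0-3, may be empty);
- orthogroup assignments: OrthoFinder (>=2.3) ``Orthogroups.tsv`` dialect — header
  ``Orthogroup`` plus one column per species, cells comma(+space)-separated
  transcript ids, possibly empty;
- species trees: newick with branch lengths, rooted and binary;
- GO annotation: TSV with columns transcript_id, species_id, go_terms
  (pipe-separated ``GO:NNNNNNN`` identifiers, possibly empty).

Every reader validates its invariants and raises :class:`FormatError` with
file/line/field context on violation; ``write`` then ``read`` is an identity on
the canonicalized content.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "TranscriptCountMatrix",
    "SampleMetadata",
    "OrthogroupMap",
    "SpeciesTree",
    "GOAnnotation",
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "read_orthogroups",
    "write_orthogroups",
    "read_newick",
    "write_newick",
    "read_go",
    "write_go",
]

TREATMENTS = ("PBS", "alum")
_GO_RE = re.compile(r"^GO:\d{7}$")


class FormatError(ValueError):
    """A file violated its format contract.

    Carries enough context (file, line/row, field) to locate the offending cell.
    """

    def __init__(self, message: str, *, path=None, line=None, field=None):
        ctx = []
        if path is not None:
            ctx.append(f"file={path}")
        if line is not None:
            ctx.append(f"line={line}")
        if field is not None:
            ctx.append(f"field={field}")
        suffix = f" [{', '.join(ctx)}]" if ctx else ""
        super().__init__(message + suffix)
        self.path, self.line, self.field = path, line, field


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class TranscriptCountMatrix:
    """Raw integer read counts for one species: transcripts x samples."""

    species_id: str
    counts: pd.DataFrame  # index = transcript ids, columns = sample ids, int64

    def __post_init__(self):
        c = self.counts
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()][0]
            raise FormatError(f"duplicate transcript id {dup!r}", field=dup)
        if c.columns.duplicated().any():
            dup = c.columns[c.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}", field=dup)
        if c.shape[1] < 2:
            raise FormatError(
                f"count matrix for {self.species_id!r} needs at least 2 samples"
            )
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            bad = ~np.isfinite(vals) | (vals != np.floor(vals))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise FormatError(
                    f"non-integer count {vals[i, j]!r}",
                    line=str(c.index[i]),
                    field=str(c.columns[j]),
                )
            self.counts = c.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise FormatError(
                f"negative count {vals[i, j]}",
                line=str(c.index[i]),
                field=str(c.columns[j]),
            )
        self.counts.index.name = "transcript_id"
        self.counts.columns.name = None

    @property
    def transcript_ids(self):
        return list(self.counts.index)

    @property
    def sample_ids(self):
        return list(self.counts.columns)


@dataclass
class SampleMetadata:
    """Per-sample design information for all species."""

    table: pd.DataFrame  # columns: sample_id, species_id, treatment, fibrosis_score

    def __post_init__(self):
        t = self.table
        required = ["sample_id", "species_id", "treatment", "fibrosis_score"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise FormatError(f"metadata missing columns {missing}")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample id {dup!r}", field=dup)
        bad = ~t["treatment"].isin(TREATMENTS)
        if bad.any():
            val = t.loc[bad, "treatment"].iloc[0]
            raise FormatError(
                f"treatment must be one of {TREATMENTS}, got {val!r}", field="treatment"
            )
        fs = t["fibrosis_score"]
        ok = fs.isna() | fs.isin([0, 1, 2, 3])
        if not ok.all():
            val = fs[~ok].iloc[0]
            raise FormatError(
                f"fibrosis_score must be 0-3 or missing, got {val!r}",
                field="fibrosis_score",
            )
        self.table = t.reset_index(drop=True)

    def for_samples(self, sample_ids) -> pd.DataFrame:
        """Metadata rows for exactly these samples; unmatched ids are an error."""
        sub = self.table.set_index("sample_id")
        missing = [s for s in sample_ids if s not in sub.index]
        if missing:
            raise FormatError(f"samples without metadata: {missing[:5]}")
        return sub.loc[list(sample_ids)].reset_index()

    def treatment_of(self, sample_ids) -> pd.Series:
        return self.for_samples(sample_ids).set_index("sample_id")["treatment"]


@dataclass
class OrthogroupMap:
    """Many-to-one (species, transcript) -> orthogroup assignment.

    ``members[og][species]`` is a tuple of bare transcript ids; cross-species
    uniqueness is guaranteed by keying on the (species, transcript) pair.
    """

    species_ids: list
    members: dict  # og_id -> {species_id -> tuple(transcript ids)}

    def __post_init__(self):
        seen = {}
        for og, per_sp in self.members.items():
            for sp, txs in per_sp.items():
                if sp not in self.species_ids:
                    raise FormatError(
                        f"unknown species {sp!r} in orthogroup {og}", field=sp
                    )
                for tx in txs:
                    key = (sp, tx)
                    if key in seen and seen[key] != og:
                        raise FormatError(
                            f"transcript {tx!r} ({sp}) assigned to both "
                            f"{seen[key]} and {og}",
                            field=tx,
                        )
                    seen[key] = og

    @property
    def orthogroup_ids(self):
        return sorted(self.members)

    def copy_numbers(self) -> pd.DataFrame:
        """Orthogroup x species matrix of per-species transcript copy numbers."""
        rows = {
            og: {sp: len(per_sp.get(sp, ())) for sp in self.species_ids}
            for og, per_sp in self.members.items()
        }
        out = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
        return out.reindex(index=self.orthogroup_ids, columns=self.species_ids)

    def core_orthogroups(self) -> list:
        """Orthogroups with at least one copy in every species."""
        cn = self.copy_numbers()
        return list(cn.index[(cn >= 1).all(axis=1)])

    def transcript_to_orthogroup(self, species_id: str) -> dict:
        """Bare transcript id -> orthogroup id for one species."""
        out = {}
        for og, per_sp in self.members.items():
            for tx in per_sp.get(species_id, ()):
                out[tx] = og
        return out


@dataclass
class SpeciesTree:
    """Rooted binary tree over species with branch lengths (substitutions/site)."""

    tree: dendropy.Tree

    def __post_init__(self):
        labels = self.leaf_labels
        if len(labels) != len(set(labels)):
            raise FormatError("duplicate leaf labels in species tree")
        for node in self.tree.preorder_node_iter():
            kids = node.child_nodes()
            if kids and len(kids) != 2:
                raise FormatError(
                    f"non-binary node with {len(kids)} children "
                    f"(resolve multifurcations upstream)"
                )
            if node.parent_node is not None and node.edge.length is None:
                raise FormatError("branch without a length")
            if node.parent_node is not None and node.edge.length < 0:
                raise FormatError(f"negative branch length {node.edge.length}")

    @property
    def leaf_labels(self):
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def restrict(self, labels) -> "SpeciesTree":
        """Prune to the given leaf set (order-independent)."""
        t = self.tree.clone(depth=1)
        keep = set(labels)
        t.retain_taxa_with_labels(sorted(keep))
        return SpeciesTree(t)

    def newick(self) -> str:
        return (
            self.tree.as_string(schema="newick", suppress_rooting=True).strip()
        )


@dataclass
class GOAnnotation:
    """Per-transcript GO term sets, keyed by (species, transcript)."""

    table: pd.DataFrame  # columns: transcript_id, species_id, go_terms (frozenset)

    def __post_init__(self):
        for terms in self.table["go_terms"]:
            for term in terms:
                if not _GO_RE.match(term):
                    raise FormatError(f"malformed GO identifier {term!r}", field=term)

    def terms_for(self, species_id: str) -> pd.Series:
        sub = self.table[self.table["species_id"] == species_id]
        return pd.Series(
            list(sub["go_terms"]), index=list(sub["transcript_id"]), dtype=object
        )


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def read_counts(path, species_id: str) -> TranscriptCountMatrix:
    """Read a transcript x sample TSV of integer counts for one species."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise FormatError("duplicate transcript id", path=path, field=str(dup))
    parsed = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        as_num = pd.to_numeric(raw[col], errors="coerce")
        bad = as_num.isna() | (as_num != np.floor(as_num)) | (as_num < 0)
        if bad.any():
            row = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"count cell {raw.loc[row, col]!r} is not a non-negative integer",
                path=path,
                line=str(row),
                field=str(col),
            )
        parsed[col] = as_num
    try:
        return TranscriptCountMatrix(species_id, parsed.astype(np.int64))
    except FormatError as err:
        raise FormatError(str(err), path=path) from err


def write_counts(tcm: TranscriptCountMatrix, path) -> None:
    tcm.counts.to_csv(path, sep="\t", index_label="transcript_id")


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------


def read_metadata(path) -> SampleMetadata:
    path = Path(path)
    t = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "species_id": str})
    if "fibrosis_score" in t.columns:
        t["fibrosis_score"] = pd.to_numeric(t["fibrosis_score"], errors="coerce")
    try:
        return SampleMetadata(t)
    except FormatError as err:
        raise FormatError(str(err), path=path) from err


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# orthogroups
# ---------------------------------------------------------------------------


def read_orthogroups(path) -> OrthogroupMap:
    """Parse the OrthoFinder >=2.3 ``Orthogroups.tsv`` dialect.

    The legacy one-line ``OG: id id id`` dialect is rejected, not silently parsed.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if cols[0] != "Orthogroup" or len(cols) < 2:
            raise FormatError(
                "expected header 'Orthogroup<TAB>species...' "
                "(legacy 'OG: id id' dialect is not supported)",
                path=path,
                line=1,
            )
        species = cols[1:]
        if len(species) != len(set(species)):
            raise FormatError("duplicate species column", path=path, line=1)
        members = {}
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(cols):
                raise FormatError(
                    f"expected {len(cols)} columns, got {len(parts)}",
                    path=path,
                    line=lineno,
                )
            og = parts[0]
            if og in members:
                raise FormatError(f"duplicate orthogroup {og}", path=path, line=lineno)
            per_sp = {}
            for sp, cell in zip(species, parts[1:]):
                txs = tuple(t.strip() for t in cell.split(",") if t.strip())
                if txs:
                    per_sp[sp] = txs
            members[og] = per_sp
    try:
        return OrthogroupMap(list(species), members)
    except FormatError as err:
        raise FormatError(str(err), path=path) from err


def write_orthogroups(og_map: OrthogroupMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(og_map.species_ids) + "\n")
        for og in og_map.orthogroup_ids:
            per_sp = og_map.members[og]
            cells = [", ".join(per_sp.get(sp, ())) for sp in og_map.species_ids]
            fh.write(og + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def read_newick(path_or_text, *, resolve_polytomies: bool = False,
                default_length: float | None = None) -> SpeciesTree:
    """Read a rooted binary newick tree.

    Multifurcations are an error unless ``resolve_polytomies`` is set (then
    resolved deterministically, zero-length edges). Missing branch lengths are
    an error unless ``default_length`` is given.
    """
    text = str(path_or_text)
    if "(" in text and ";" in text:
        tree = dendropy.Tree.get(data=text, schema="newick")
        path = None
    else:
        path = Path(path_or_text)
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    tree.is_rooted = True
    if resolve_polytomies:
        tree.resolve_polytomies()
    if default_length is not None:
        for edge in tree.preorder_edge_iter():
            if edge.head_node.parent_node is not None and edge.length is None:
                edge.length = default_length
    try:
        return SpeciesTree(tree)
    except FormatError as err:
        raise FormatError(str(err), path=path) from err


def write_newick(tree: SpeciesTree, path=None) -> str:
    text = tree.newick()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# GO annotation
# ---------------------------------------------------------------------------


def read_go(path) -> GOAnnotation:
    path = Path(path)
    t = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = ["transcript_id", "species_id", "go_terms"]
    missing = [c for c in required if c not in t.columns]
    if missing:
        raise FormatError(f"GO map missing columns {missing}", path=path)
    t["go_terms"] = [
        frozenset(x for x in cell.split("|") if x) for cell in t["go_terms"]
    ]
    try:
        return GOAnnotation(t)
    except FormatError as err:
        raise FormatError(str(err), path=path) from err


def write_go(anno: GOAnnotation, path) -> None:
    out = anno.table.copy()
    out["go_terms"] = ["|".join(sorted(terms)) for terms in out["go_terms"]]
    out.to_csv(path, sep="\t", index=False)
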