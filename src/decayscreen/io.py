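"""Readers and writers for the pipeline's on-disk formats.

Formats: rooted newick trees with branch lengths (dendropy), gapped
amino-acid FASTA (Biopython), and headered TSV tables with schema
validation. All writers emit a deterministic row order (og_id, then
species_id, lexicographic) so identical inputs give byte-identical files.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A file failed schema or format validation."""


# column -> pandas dtype for every table the pipeline reads or writes
SCHEMAS: dict[str, dict[str, str]] = {
    "traits": {
        "species_id": "string",
        "bristle_state": "string",
        "p_miss": "float64",
        "dist_to_focal": "float64",
    },
    "scores": {"og_id": "string", "species_id": "string", "bitscore": "float64"},
    "annotations": {
        "og_id": "string",
        "category": "string",
        "adult_biased": "boolean",
        "focal_len": "int64",
    },
    "truth": {
        "og_id": "string",
        "category": "string",
        "L": "float64",
        "R": "float64",
        "focal_len": "int64",
        "mult_present": "float64",
        "mult_reduced": "float64",
        "mult_absent": "float64",
    },
    "fits": {
        "og_id": "string",
        "L": "float64",
        "R": "float64",
        "n_used": "int64",
        "converged": "boolean",
        "spurious": "boolean",
    },
    "residuals": {
        "og_id": "string",
        "species_id": "string",
        "t": "float64",
        "residual": "float64",
    },
    "residual_summaries": {
        "og_id": "string",
        "bristle_state": "string",
        "median_residual": "float64",
        "n_species": "int64",
    },
    "detectability": {
        "og_id": "string",
        "threshold_bits": "float64",
        "p_detect": "float64",
        "detectable": "boolean",
    },
    "presence_fits": {
        "og_id": "string",
        "bristle_state": "string",
        "post_mean": "float64",
        "ci_lo": "float64",
        "ci_hi": "float64",
        "sigma_p_mean": "float64",
        "ess_min": "float64",
        "fitted": "boolean",
        "skip_reason": "string",
    },
}

_SORT_KEYS = ["og_id", "species_id", "bristle_state", "category", "stratum"]


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a TSV table and validate it against a named schema.

    Raises FormatError naming any missing required column.
    """
    cols = SCHEMAS[schema]
    try:
        df = pd.read_csv(path, sep="\t", dtype="string")
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message has context
        raise FormatError(f"{path}: malformed TSV: {exc}") from exc
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    bool_map = {"True": True, "False": False, "true": True, "false": False}
    for col, dtype in cols.items():
        try:
            if dtype == "boolean":
                df[col] = df[col].map(bool_map).astype("boolean")
            else:
                df[col] = df[col].astype(dtype)
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: column {col!r} not parseable as {dtype}: {exc}") from exc
    return df


def write_table(df: pd.DataFrame, path: str | Path, schema: str | None = None) -> None:
    """Write a TSV with a header and deterministic row order."""
    if schema is not None:
        missing = [c for c in SCHEMAS[schema] if c not in df.columns]
        if missing:
            raise FormatError(f"refusing to write {path}: missing column(s) {missing}")
    keys = [k for k in _SORT_KEYS if k in df.columns]
    if keys:
        df = df.sort_values(keys, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_tree(path: str | Path) -> dendropy.Tree:
    """Parse a rooted newick tree with branch lengths; tips must be unique."""
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise FormatError(f"{path}: duplicate tip labels")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is None:
            raise FormatError(f"{path}: edge above {edge.head_node} has no branch length")
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree_to_newick(tree))


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True)


def validate_ultrametric(tree: dendropy.Tree, tol: float = 1e-6) -> float:
    """Return the max root-to-tip depth spread; raise if it exceeds tol."""
    depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
    spread = max(depths) - min(depths)
    if spread > tol:
        raise FormatError(f"tree is not ultrametric: max depth spread {spread:.3g} > {tol:.3g}")
    return spread


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly gapped) amino-acid FASTA into an ordered id->sequence map."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = str(rec.seq)
    return records


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def scores_to_long(df: pd.DataFrame) -> pd.DataFrame:
    """Normalise a scores table: empty bitscore fields mean 'absent' (NaN kept)."""
    out = df.copy()
    out["present"] = out["bitscore"].notna()
    return out


def fasta_string(seqs: dict[str, str]) -> str:
    buf = _io.StringIO()
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()
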