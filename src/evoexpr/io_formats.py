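"""Readers and writers for every external format the pipeline touches.

All tabular formats are TSV with a header row; lines starting with ``#`` are
metadata comments and are ignored on read. Domain coordinates are 1-based
inclusive (Pfam convention). Gene/sample identifiers are case-sensitive
opaque strings.
"""

from __future__ import annotations

import io
from pathlib import Path

import dendropy
import pandas as pd

from .types import (
    AgeTable,
    DisorderTrack,
    Domain,
    ExpressionDataset,
    FormatError,
    GeneRecord,
    SpeciesTree,
)

_GRADES = {"old", "mid", "young"}


# ---------------------------------------------------------------- species tree


def read_species_tree(path: str | Path) -> SpeciesTree:
    """Parse a Newick species tree; every node must carry a unique name."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return parse_species_tree(path.read_text())


def parse_species_tree(newick: str) -> SpeciesTree:
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"invalid Newick: {exc}") from exc
    tree.is_rooted = True
    return SpeciesTree(tree)


def write_species_tree(tree: SpeciesTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------- TSV helpers


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def _write_tsv(df: pd.DataFrame, path: str | Path, header_comments: list[str] = ()) -> None:
    buf = io.StringIO()
    for line in header_comments:
        buf.write(f"# {line}\n")
    df.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------- gene records


def read_gene_records(path: str | Path) -> list[GeneRecord]:
    """Read domain-annotation TSV into gene records (one row per domain hit).

    Rows with an empty ``family_id`` declare a domain-free protein.
    Overlapping hits on the same protein are resolved by keeping the longer
    hit (ties by earlier start, then family id).
    """
    df = _read_tsv(
        path,
        ["gene_id", "protein_id", "species", "protein_length", "family_id", "start", "end", "family_class"],
    )
    records: dict[str, GeneRecord] = {}
    pending: dict[str, list[Domain]] = {}
    for row in df.itertuples(index=False):
        gid = row.gene_id
        if gid not in records:
            records[gid] = GeneRecord(
                gene_id=gid,
                species=row.species,
                protein_id=row.protein_id,
                protein_length=int(row.protein_length),
            )
            pending[gid] = []
        rec = records[gid]
        if row.protein_id != rec.protein_id:
            raise FormatError(
                f"gene {gid}: multiple proteins ({rec.protein_id}, {row.protein_id}); "
                "supply only the longest isoform"
            )
        if row.family_id == "":
            continue
        cls = row.family_class
        if cls not in {"KRAB", "C2H2", "other"}:
            raise FormatError(f"gene {gid}: unknown family_class {cls!r}")
        pending[gid].append(
            Domain(
                family_id=row.family_id,
                start=int(row.start),
                end=int(row.end),
                is_krab=cls == "KRAB",
                is_c2h2=cls == "C2H2",
            )
        )
    out = []
    for gid, rec in records.items():
        rec.domains = resolve_overlaps(pending[gid])
        rec.__post_init__()  # re-validate coordinates against protein length
        out.append(rec)
    out.sort(key=lambda r: r.gene_id)
    return out


def resolve_overlaps(domains: list[Domain]) -> list[Domain]:
    """Drop the shorter hit of every overlapping pair; keep sequence order."""
    ranked = sorted(domains, key=lambda d: (-d.length, d.start, d.family_id))
    kept: list[Domain] = []
    for d in ranked:
        if all(d.end < k.start or d.start > k.end for k in kept):
            kept.append(d)
    kept.sort(key=lambda d: d.start)
    return kept


def write_gene_records(records: list[GeneRecord], path: str | Path) -> None:
    rows = []
    for rec in sorted(records, key=lambda r: r.gene_id):
        if not rec.domains:
            rows.append((rec.gene_id, rec.protein_id, rec.species, rec.protein_length, "", "", "", ""))
        for d in rec.domains:
            cls = "KRAB" if d.is_krab else ("C2H2" if d.is_c2h2 else "other")
            rows.append(
                (rec.gene_id, rec.protein_id, rec.species, rec.protein_length, d.family_id, d.start, d.end, cls)
            )
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "protein_id", "species", "protein_length", "family_id", "start", "end", "family_class"],
    )
    _write_tsv(df, path, ["coordinates are 1-based inclusive"])


# ------------------------------------------------------------- disorder tracks


def read_disorder_tracks(path: str | Path) -> dict[str, DisorderTrack]:
    df = _read_tsv(path, ["protein_id", "labels"])
    tracks: dict[str, DisorderTrack] = {}
    for row in df.itertuples(index=False):
        if row.protein_id in tracks:
            raise FormatError(f"duplicate disorder track for {row.protein_id!r}")
        tracks[row.protein_id] = DisorderTrack(row.protein_id, row.labels)
    return tracks


def write_disorder_tracks(tracks: dict[str, DisorderTrack], path: str | Path) -> None:
    df = pd.DataFrame(
        [(t.protein_id, t.labels) for t in tracks.values()],
        columns=["protein_id", "labels"],
    ).sort_values("protein_id", ignore_index=True)
    _write_tsv(df, path)


# ------------------------------------------------------------------ age tables


def read_age_table(path: str | Path) -> AgeTable:
    df = _read_tsv(path, ["gene_id", "age_taxon", "age_grade"])
    bad = set(df["age_grade"]) - _GRADES
    if bad:
        raise FormatError(f"unknown age grade(s): {sorted(bad)}")
    if "znf_grade" in df.columns:
        bad = set(df.loc[df["znf_grade"] != "", "znf_grade"]) - _GRADES
        if bad:
            raise FormatError(f"unknown zinc-finger grade(s): {sorted(bad)}")
    df = df.replace({"": None}).set_index("gene_id")
    return AgeTable(df)


def write_age_table(ages: AgeTable, path: str | Path) -> None:
    df = ages.table.reset_index().fillna("")
    df = df.sort_values("gene_id", ignore_index=True)
    _write_tsv(df, path)


# -------------------------------------------------------- expression datasets


def read_expression_dataset(
    counts_path: str | Path,
    tpm_path: str | Path,
    meta_path: str | Path,
    dataset_id: str | None = None,
    species: str | None = None,
) -> ExpressionDataset:
    """Load one dataset from counts/TPM matrix TSVs plus sample metadata.

    Matrices have a ``gene_id`` first column and one column per sample.
    Metadata columns: sample_id, category, stage_order, batch_id and
    optionally dataset_id, species (used when not given as arguments).
    Genes are sorted lexicographically for a deterministic order.
    """
    counts = _read_matrix(counts_path)
    tpm = _read_matrix(tpm_path)
    meta = _read_tsv(meta_path, ["sample_id", "category", "stage_order", "batch_id"])
    if meta["sample_id"].duplicated().any():
        raise FormatError(f"{meta_path}: duplicate sample ids")
    meta = meta.set_index("sample_id")
    meta["stage_order"] = meta["stage_order"].astype(int)
    if dataset_id is None:
        dataset_id = meta["dataset_id"].iloc[0] if "dataset_id" in meta.columns else Path(counts_path).stem
    if species is None:
        species = meta["species"].iloc[0] if "species" in meta.columns else "unknown"
    if set(counts.columns) != set(tpm.columns) or list(counts.index) != list(tpm.index):
        raise FormatError("counts and TPM matrices do not share gene/sample indices")
    return ExpressionDataset(
        dataset_id=dataset_id,
        species=species,
        counts=counts,
        tpm=tpm[counts.columns],
        samples=meta[["category", "stage_order", "batch_id"]],
    )


def _read_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.name != "gene_id":
        raise FormatError(f"{path}: first column must be 'gene_id'")
    if df.isna().any().any():
        raise FormatError(f"{path}: missing values in matrix")
    return df.sort_index()


def write_expression_dataset(ds: ExpressionDataset, prefix: str | Path) -> tuple[Path, Path, Path]:
    """Write <prefix>.counts.tsv, <prefix>.tpm.tsv and <prefix>.meta.tsv."""
    prefix = Path(prefix)
    paths = (
        prefix.with_suffix(".counts.tsv"),
        prefix.with_suffix(".tpm.tsv"),
        prefix.with_suffix(".meta.tsv"),
    )
    ds.counts.rename_axis("gene_id").to_csv(paths[0], sep="\t")
    ds.tpm.rename_axis("gene_id").to_csv(paths[1], sep="\t", float_format="%.6g")
    meta = ds.samples.copy()
    meta.insert(0, "dataset_id", ds.dataset_id)
    meta.insert(1, "species", ds.species)
    meta.rename_axis("sample_id").reset_index().to_csv(paths[2], sep="\t", index=False)
    return paths


# ------------------------------------------------------------------ edge lists


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Protein-protein (or gene-gene) edge list: protein_a, protein_b, source."""
    df = _read_tsv(path, ["protein_a", "protein_b"])
    if "source" not in df.columns:
        df["source"] = ""
    if (df["protein_a"] == df["protein_b"]).any():
        raise FormatError(f"{path}: self-edge in edge list")
    return df


def write_edge_list(df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(df, path)
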