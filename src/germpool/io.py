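"""Domain types and delimited-text readers/writers.

The native interchange formats are plain delimited text:

* pool count table — TSV with columns ``contig``, ``position``, ``ref``,
  ``alt`` and then per-pool ``<pool>_depth`` / ``<pool>_alt_prop`` pairs;
* genotype matrix — CSV with accession rows, locus columns and calls in
  ``{AA, AB, BB, NA}`` (coded internally as alt-allele dosage 0/1/2 with a
  distinct missing sentinel);
* accession metadata — CSV with ``accession_id``, ``botanical_race`` and an
  optional ``pool`` column;
* trees — Newick with branch lengths and integer bootstrap labels;
* reports — JSON.

Coordinates are 1-based positions on named contigs; the reference contig
orientation is canonical, so no strand handling is needed.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call; never conflated with homozygous ref.
MISSING: int = -1

CALL_TO_CODE = {"AA": 0, "AB": 1, "BB": 2, "NA": MISSING}
CODE_TO_CALL = {v: k for k, v in CALL_TO_CODE.items()}

RACES = ("Guatemalan", "Mexican", "WestIndian")


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


@dataclass(frozen=True, order=True)
class Locus:
    """A biallelic site on a reference contig (1-based position)."""

    contig_id: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles identical at {self.contig_id}:{self.position}")

    @property
    def name(self) -> str:
        return f"{self.contig_id}:{self.position}"


@dataclass
class PoolCountTable:
    """Per-locus, per-pool read depth and alternative-allele proportion.

    ``alt_prop`` is defined only where ``depth > 0``; undefined cells hold
    NaN.  This is the discovery-stage input: each pool is the sequenced DNA
    mixture of one subpopulation (botanical race), and the read proportion
    of the alternative allele estimates the pool allele frequency.
    """

    loci: list[Locus]
    pool_names: list[str]
    depth: np.ndarray  # (n_loci, n_pools) int
    alt_prop: np.ndarray  # (n_loci, n_pools) float, NaN where depth == 0

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        self.alt_prop = np.asarray(self.alt_prop, dtype=float)
        n_loci, n_pools = len(self.loci), len(self.pool_names)
        if self.depth.shape != (n_loci, n_pools) or self.alt_prop.shape != (n_loci, n_pools):
            raise ValueError("depth/alt_prop shapes inconsistent with loci and pools")
        if (self.depth < 0).any():
            raise ValueError("negative read depth")
        defined = self.depth > 0
        props = self.alt_prop[defined]
        if ((props < 0) | (props > 1)).any():
            raise ValueError("alt_prop outside [0, 1]")

    @property
    def n_loci(self) -> int:
        return len(self.loci)


@dataclass
class PoolCallTable:
    """Per-locus, per-pool polymorphism call in {AA, AB, BB, NA}.

    NA marks pools whose depth fell outside the screening bounds.
    """

    loci: list[Locus]
    pool_names: list[str]
    call: np.ndarray  # (n_loci, n_pools) int8 coded with CALL_TO_CODE

    def __post_init__(self) -> None:
        self.call = np.asarray(self.call, dtype=np.int8)
        if self.call.shape != (len(self.loci), len(self.pool_names)):
            raise ValueError("call shape inconsistent with loci and pools")
        valid = set(CALL_TO_CODE.values())
        if not set(np.unique(self.call)).issubset(valid):
            raise ValueError("call codes outside {AA, AB, BB, NA} alphabet")

    def calls_as_text(self) -> pd.DataFrame:
        txt = np.vectorize(CODE_TO_CALL.get)(self.call)
        return pd.DataFrame(txt, index=[l.name for l in self.loci], columns=self.pool_names)


@dataclass
class GenotypeMatrix:
    """Accession x locus diploid calls coded as alt-allele dosage.

    ``geno[i, j]`` counts copies of the alternative allele: 0 (AA), 1 (AB),
    2 (BB), or :data:`MISSING` for a failed call.
    """

    accessions: list[str]
    loci: list[Locus]
    geno: np.ndarray  # (n_accessions, n_loci) int8

    def __post_init__(self) -> None:
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.shape != (len(self.accessions), len(self.loci)):
            raise ValueError("geno shape inconsistent with accessions and loci")
        valid = {0, 1, 2, MISSING}
        if not set(np.unique(self.geno)).issubset(valid):
            raise ValueError("genotype codes outside {0, 1, 2, missing}")
        if len(set(self.accessions)) != len(self.accessions):
            raise ValueError("duplicate accession IDs")

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    def called_mask(self) -> np.ndarray:
        return self.geno != MISSING

    def alt_allele_frequency(self) -> np.ndarray:
        """Per-locus alt-allele frequency over called accessions (NaN if none)."""
        called = self.called_mask()
        n = called.sum(axis=0)
        alt = np.where(called, self.geno, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)

    def subset_loci(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(
            accessions=list(self.accessions),
            loci=[self.loci[i] for i in idx],
            geno=self.geno[:, idx].copy(),
        )

    def subset_accessions(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(
            accessions=[self.accessions[i] for i in idx],
            loci=list(self.loci),
            geno=self.geno[idx, :].copy(),
        )


@dataclass
class AccessionMetadata:
    """Botanical race labels and pool membership per accession."""

    table: pd.DataFrame  # index accession_id; columns botanical_race, pool

    VALID_RACES = set(RACES) | {"unidentified", "cultivar"}

    def __post_init__(self) -> None:
        required = {"botanical_race"}
        if not required.issubset(self.table.columns):
            raise FormatError("metadata requires a botanical_race column")
        labels = set(self.table["botanical_race"])
        # generic RaceN labels appear when simulating other than 3 races
        bad = {l for l in labels - self.VALID_RACES if not str(l).startswith("Race")}
        if bad:
            raise ValueError(f"unknown botanical race labels: {sorted(bad)}")
        if "pool" not in self.table.columns:
            self.table = self.table.assign(pool=pd.NA)

    @property
    def accessions(self) -> list[str]:
        return list(self.table.index)

    def race_of(self, accession: str) -> str:
        return str(self.table.loc[accession, "botanical_race"])

    def pool_members(self, pool: str) -> list[str]:
        col = self.table["pool"]
        return list(self.table.index[col == pool])

    def pools(self) -> list[str]:
        return sorted(set(self.table["pool"].dropna()))


# ---------------------------------------------------------------------------
# readers / writers


def _locus_from_row(contig: str, position, ref: str, alt: str, line_no: int) -> Locus:
    try:
        return Locus(str(contig), int(position), str(ref), str(alt))
    except (TypeError, ValueError) as exc:
        raise FormatError(f"line {line_no}: bad locus fields ({exc})") from exc


def read_pool_count_table(path: str | Path) -> PoolCountTable:
    """Read a TSV of per-pool read depths and alt-allele proportions.

    Expected columns: ``contig``, ``position``, ``ref``, ``alt``, then for
    each pool ``<pool>_depth`` and ``<pool>_alt_prop``.  A depth-0 cell may
    leave its alt_prop empty (recorded as undefined).
    """
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    required = ["contig", "position", "ref", "alt"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing required column(s) {missing_cols}")
    depth_cols = [c for c in df.columns if c.endswith("_depth")]
    pools = [c[: -len("_depth")] for c in depth_cols]
    if not pools:
        raise FormatError(f"{path}: no <pool>_depth columns found")
    for p in pools:
        if f"{p}_alt_prop" not in df.columns:
            raise FormatError(f"{path}: pool {p!r} has depth but no {p}_alt_prop column")

    loci = [
        _locus_from_row(row.contig, row.position, row.ref, row.alt, i + 2)
        for i, row in enumerate(df.itertuples(index=False))
    ]
    depth = df[[f"{p}_depth" for p in pools]].to_numpy(dtype=np.int64)
    alt_prop = df[[f"{p}_alt_prop" for p in pools]].to_numpy(dtype=float)
    # alt_prop is meaningless without reads; normalize those cells to NaN
    alt_prop = np.where(depth > 0, alt_prop, np.nan)
    bad = (depth > 0) & (np.isnan(alt_prop) | (alt_prop < 0) | (alt_prop > 1))
    if bad.any():
        locus_i, pool_i = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: line {locus_i + 2}: alt_prop for pool {pools[pool_i]!r} "
            "missing or outside [0, 1] at positive depth"
        )
    return PoolCountTable(loci=loci, pool_names=pools, depth=depth, alt_prop=alt_prop)


def write_pool_count_table(table: PoolCountTable, path: str | Path) -> None:
    cols: dict[str, object] = {
        "contig": [l.contig_id for l in table.loci],
        "position": [l.position for l in table.loci],
        "ref": [l.ref_allele for l in table.loci],
        "alt": [l.alt_allele for l in table.loci],
    }
    for j, p in enumerate(table.pool_names):
        cols[f"{p}_depth"] = table.depth[:, j]
        cols[f"{p}_alt_prop"] = table.alt_prop[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6g")


def _parse_locus_name(name: str, line_no: int = 0) -> Locus:
    try:
        contig, rest = name.rsplit(":", 1)
        if "_" in rest:
            pos, alleles = rest.split("_", 1)
            ref, alt = alleles.split(">")
        else:
            pos, ref, alt = rest, "A", "C"  # alleles unknown from bare name
        return Locus(contig, int(pos), ref, alt)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"cannot parse locus name {name!r}: {exc}") from exc


def locus_column_name(locus: Locus) -> str:
    return f"{locus.contig_id}:{locus.position}_{locus.ref_allele}>{locus.alt_allele}"


def read_genotype_matrix(path: str | Path) -> GenotypeMatrix:
    """Read an accession x locus CSV of {AA, AB, BB, NA} calls.

    Column headers name loci as ``contig:pos_REF>ALT`` (or bare
    ``contig:pos``); row index is the accession ID.
    """
    try:
        # "NA" is a genotype symbol, not a pandas missing value
        df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty genotype matrix") from exc
    if df.empty:
        raise FormatError(f"{path}: empty genotype matrix")
    values = df.to_numpy()
    known = np.isin(values, list(CALL_TO_CODE))
    if not known.all():
        i, j = np.argwhere(~known)[0]
        raise FormatError(
            f"{path}: unknown call {values[i, j]!r} for accession "
            f"{df.index[i]!r} at locus {df.columns[j]!r}"
        )
    geno = np.vectorize(CALL_TO_CODE.get)(values).astype(np.int8)
    loci = [_parse_locus_name(c) for c in df.columns]
    return GenotypeMatrix(accessions=[str(a) for a in df.index], loci=loci, geno=geno)


def write_genotype_matrix(genos: GenotypeMatrix, path: str | Path) -> None:
    txt = np.vectorize(CODE_TO_CALL.get)(genos.geno)
    df = pd.DataFrame(
        txt, index=genos.accessions, columns=[locus_column_name(l) for l in genos.loci]
    )
    df.index.name = "accession_id"
    df.to_csv(path)


def read_metadata(path: str | Path) -> AccessionMetadata:
    df = pd.read_csv(path, index_col="accession_id", dtype=str)
    return AccessionMetadata(table=df)


def write_metadata(meta: AccessionMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, index_label="accession_id")


def write_vcf(genos: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF export (GT field only), one sample per accession.

    Interoperability output only; not a pipeline input.
    """
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(genos.accessions) + "\n")
        for j, locus in enumerate(genos.loci):
            calls = "\t".join(gt_map[int(g)] for g in genos.geno[:, j])
            fh.write(
                f"{locus.contig_id}\t{locus.position}\t{locus.name}\t"
                f"{locus.ref_allele}\t{locus.alt_allele}\t.\t.\t.\tGT\t{calls}\n"
            )


def write_newick(dendrogram, path: str | Path | None = None) -> str:
    """Serialize a dendrogram as Newick with branch lengths and support labels.

    Internal nodes carry integer bootstrap counts (when present) as node
    labels.  Returns the Newick string; writes it if ``path`` is given.
    """
    if len(dendrogram.leaf_names) < 2:
        raise ValueError("dendrogram must have at least 2 leaves")
    if len(set(dendrogram.leaf_names)) != len(dendrogram.leaf_names):
        raise ValueError("duplicate leaf names")
    newick = dendrogram.to_newick()
    if path is not None:
        Path(path).write_text(newick + "\n")
    return newick


def write_json_report(report: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, default=_default, allow_nan=True) + "\n")
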