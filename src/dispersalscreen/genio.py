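"""Reading, validation and quality filtering of the study's data formats.

Handles DArT-style SNP call tables (one-row 0/1/2 and two-row
presence/absence encodings), plain-text VCF v4.2, chloroplast alignments
(FASTA), chloroplast variant tables with coverage/consensus/annotation
fields, sample metadata and species trait tables.  All readers accept
gzip-compressed input transparently.

Genotypes are coded as the count of the alternate allele (0, 1, 2) with a
single missing sentinel (:data:`MISSING`).  Downstream code must branch on
the sentinel explicitly; it is never silently treated as a zero.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Sentinel for a missing diploid call.  Distinct from every valid call.
MISSING: int = -1

#: Fruit whose maximum width is at least this many millimetres are "large".
#: Large fruit cannot be swallowed whole by the volant frugivores of the
#: southern subtropical rainforests, so large-fruited species lost their
#: long-distance dispersal vector with the megafauna extinction.
LARGE_FRUIT_MIN_WIDTH_MM: float = 30.0

_VALID_CALLS = frozenset({0, 1, 2, MISSING})


class GenodataError(ValueError):
    """Raised for malformed or inconsistent input data."""


class EmptyResultError(GenodataError):
    """Raised when a filter removes every marker or variant."""


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Diploid SNP calls for a set of samples at a set of loci.

    Parameters
    ----------
    sample_ids, locus_ids
        Ordered identifiers; order is preserved by every operation.
    calls
        ``(n_samples, n_loci)`` integer array with entries in
        ``{0, 1, 2, MISSING}`` counting copies of the alternate allele.
    reproducibility, call_rate
        Optional per-locus QC metadata in ``[0, 1]`` (DArT reports the
        fraction of technical replicates with a consistent score, and the
        fraction of samples with a non-missing score).
    """

    sample_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    reproducibility: np.ndarray | None = None
    call_rate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise GenodataError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        bad = ~np.isin(self.calls, list(_VALID_CALLS))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenodataError(
                f"invalid genotype code {self.calls[i, j]} at sample "
                f"{self.sample_ids[i]!r}, locus {self.locus_ids[j]!r}"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise GenodataError("duplicate sample ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise GenodataError("duplicate locus ids")
        for name in ("reproducibility", "call_rate"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (len(self.locus_ids),):
                    raise GenodataError(f"{name} length != number of loci")
                if ((v < 0) | (v > 1)).any():
                    raise GenodataError(f"{name} values outside [0, 1]")
                setattr(self, name, v)
        if self.call_rate is not None:
            observed = self.observed_call_rate()
            off = np.abs(self.call_rate - observed) > 1e-6
            if off.any():
                j = int(np.flatnonzero(off)[0])
                raise GenodataError(
                    f"call_rate metadata disagrees with the observed non-missing "
                    f"fraction (locus {self.locus_ids[j]!r}: stated "
                    f"{self.call_rate[j]:.4f}, observed {observed[j]:.4f})"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def observed_call_rate(self) -> np.ndarray:
        """Per-locus fraction of samples with a non-missing call."""
        return (self.calls != MISSING).mean(axis=0)

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            locus_ids=[self.locus_ids[i] for i in np.flatnonzero(keep)]
            if keep.dtype == bool
            else [self.locus_ids[i] for i in keep],
            calls=self.calls[:, keep],
            reproducibility=None
            if self.reproducibility is None
            else self.reproducibility[keep],
            call_rate=None if self.call_rate is None else self.call_rate[keep],
        )


@dataclass
class MarkerFilterReport:
    n_input: int
    n_kept: int
    n_fail_reproducibility: int
    n_fail_call_rate: int
    n_fail_both: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def filter_markers(
    gm: GenotypeMatrix,
    min_reproducibility: float = 0.96,
    min_call_rate: float = 0.80,
) -> tuple[GenotypeMatrix, MarkerFilterReport]:
    """Apply the standard DArT marker QC filter.

    A locus is retained iff ``reproducibility >= min_reproducibility`` AND
    ``call_rate >= min_call_rate``; boundary values are retained.  If the
    table carries no call-rate column it is recomputed from the observed
    missingness; an absent reproducibility column with an active threshold
    is a configuration error.  The sample set is never changed.
    """
    for name, v in (("min_reproducibility", min_reproducibility), ("min_call_rate", min_call_rate)):
        if not 0.0 <= v <= 1.0:
            raise GenodataError(f"{name} must be in [0, 1], got {v}")
    call_rate = gm.call_rate
    if call_rate is None:
        call_rate = gm.observed_call_rate()
    if gm.reproducibility is None:
        if min_reproducibility > 0.0:
            raise GenodataError(
                "reproducibility metadata absent but min_reproducibility > 0; "
                "supply QC metadata or set the threshold to 0"
            )
        repro = np.ones(gm.n_loci)
    else:
        repro = gm.reproducibility
    ok_r = repro >= min_reproducibility
    ok_c = call_rate >= min_call_rate
    keep = ok_r & ok_c
    report = MarkerFilterReport(
        n_input=gm.n_loci,
        n_kept=int(keep.sum()),
        n_fail_reproducibility=int((~ok_r & ok_c).sum()),
        n_fail_call_rate=int((ok_r & ~ok_c).sum()),
        n_fail_both=int((~ok_r & ~ok_c).sum()),
    )
    if report.n_kept == 0:
        raise EmptyResultError("marker filter removed every locus")
    return gm.subset_loci(keep), report


# ---------------------------------------------------------------------------
# Genotype readers / writers
# ---------------------------------------------------------------------------

_GT_CODE = {"0/0": 0, "0|0": 0, "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1,
            "1/1": 2, "1|1": 2, "./.": MISSING, ".|.": MISSING, ".": MISSING}


def read_genotypes(path: str | Path, dialect: str, split_multiallelic: bool = False) -> GenotypeMatrix:
    """Read a genotype matrix from a DArT-style CSV or a VCF v4.2 file.

    ``dialect`` is ``"dart_csv"`` or ``"vcf"``.  Sample and locus ordering
    follow the file.  Multiallelic VCF records are rejected unless
    ``split_multiallelic`` is set, in which case each alternate allele
    becomes its own biallelic locus (other alternates coded missing).
    """
    if dialect == "vcf":
        return _read_vcf(path, split_multiallelic)
    if dialect == "dart_csv":
        return _read_dart_csv(path)
    raise GenodataError(f"unknown dialect {dialect!r}; expected 'dart_csv' or 'vcf'")


def _read_vcf(path: str | Path, split_multiallelic: bool) -> GenotypeMatrix:
    sample_ids: list[str] = []
    locus_ids: list[str] = []
    rows: list[np.ndarray] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                parts = line.split("\t")
                if len(parts) < 10:
                    raise GenodataError(f"{path}:{lineno}: VCF has no sample columns")
                sample_ids = parts[9:]
                continue
            if not sample_ids:
                raise GenodataError(f"{path}:{lineno}: record before #CHROM header")
            parts = line.split("\t")
            chrom, pos, vid, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            fmt = parts[8].split(":")
            if "GT" not in fmt:
                raise GenodataError(f"{path}:{lineno}: record lacks GT field")
            gt_idx = fmt.index("GT")
            alts = alt.split(",")
            gts = [p.split(":")[gt_idx] for p in parts[9:]]
            if len(gts) != len(sample_ids):
                raise GenodataError(f"{path}:{lineno}: wrong number of sample columns")
            if len(alts) > 1 and not split_multiallelic:
                raise GenodataError(
                    f"{path}:{lineno}: multiallelic record at {chrom}:{pos}; "
                    "set split_multiallelic=True to split"
                )
            for ai, a in enumerate(alts, start=1):
                row = np.empty(len(gts), dtype=np.int16)
                for si, gt in enumerate(gts):
                    sep = "|" if "|" in gt else "/"
                    fields = gt.split(sep)
                    if len(fields) != 2:
                        raise GenodataError(
                            f"{path}:{lineno}: sample {sample_ids[si]!r} has "
                            f"ploidy {len(fields)}, expected diploid"
                        )
                    if "." in fields:
                        row[si] = MISSING
                        continue
                    try:
                        alleles = [int(f) for f in fields]
                    except ValueError:
                        raise GenodataError(
                            f"{path}:{lineno}: unknown genotype code {gt!r} "
                            f"for sample {sample_ids[si]!r}"
                        ) from None
                    if any(x > len(alts) for x in alleles):
                        raise GenodataError(
                            f"{path}:{lineno}: allele index out of range in {gt!r}"
                        )
                    if len(alts) > 1 and any(x not in (0, ai) for x in alleles):
                        row[si] = MISSING  # other alternate at a split record
                    else:
                        row[si] = sum(1 for x in alleles if x == ai)
                name = vid if vid not in (".", "") else f"{chrom}:{pos}"
                if len(alts) > 1:
                    name = f"{name}_{a}"
                locus_ids.append(name)
                rows.append(row)
    if not rows:
        raise GenodataError(f"{path}: no variant records")
    calls = np.stack(rows, axis=1)
    return GenotypeMatrix(sample_ids=sample_ids, locus_ids=locus_ids, calls=calls)


def _read_dart_csv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, dtype=str)
    cols = list(df.columns)
    if not cols:
        raise GenodataError(f"{path}: empty table")
    locus_col = cols[0]
    meta_cols = [c for c in cols[1:] if c.lower() in ("reproducibility", "repavg", "call_rate", "callrate")]
    sample_cols = [c for c in cols[1:] if c not in meta_cols]
    if not sample_cols:
        raise GenodataError(f"{path}: no sample columns")
    two_row = df[locus_col].duplicated().any()
    if two_row:
        return _collapse_two_row(path, df, locus_col, meta_cols, sample_cols)
    locus_ids = df[locus_col].tolist()
    calls = np.full((len(sample_cols), len(locus_ids)), MISSING, dtype=np.int16)
    for j, (_, row) in enumerate(df.iterrows()):
        for i, c in enumerate(sample_cols):
            calls[i, j] = _parse_dart_call(row[c], path, j, c)
    repro, call_rate = _dart_meta(df, meta_cols)
    return GenotypeMatrix(sample_cols, locus_ids, calls, repro, call_rate)


def _parse_dart_call(v, path, row_idx, col) -> int:
    if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v):
        return MISSING
    s = str(v).strip()
    if s in ("", "-", "NA", "."):
        return MISSING
    try:
        x = int(s)
    except ValueError:
        raise GenodataError(f"{path}: row {row_idx}, column {col!r}: bad call {v!r}") from None
    if x not in (0, 1, 2):
        raise GenodataError(f"{path}: row {row_idx}, column {col!r}: bad call {v!r}")
    return x


def _dart_meta(df: pd.DataFrame, meta_cols: list[str]):
    repro = call_rate = None
    for c in meta_cols:
        vals = pd.to_numeric(df.drop_duplicates(subset=df.columns[0])[c]
                             if df[df.columns[0]].duplicated().any() else df[c]).to_numpy(float)
        if c.lower() in ("reproducibility", "repavg"):
            repro = vals
        else:
            call_rate = vals
    return repro, call_rate


def _collapse_two_row(path, df, locus_col, meta_cols, sample_cols) -> GenotypeMatrix:
    """Collapse DArT two-row presence/absence pairs to 0/1/2 calls.

    Row 1 scores presence of the reference allele, row 2 of the alternate:
    (1,0) -> 0, (1,1) -> 1, (0,1) -> 2, (0,0) -> missing.  Conflicting
    pairs (scores outside {0,1}) are set missing and logged.
    """
    groups = list(df.groupby(locus_col, sort=False))
    locus_ids = [g[0] for g in groups]
    calls = np.full((len(sample_cols), len(locus_ids)), MISSING, dtype=np.int16)
    n_conflict = 0
    for j, (lid, sub) in enumerate(groups):
        if len(sub) != 2:
            raise GenodataError(f"{path}: locus {lid!r} has {len(sub)} rows, expected 2")
        r1, r2 = sub.iloc[0], sub.iloc[1]
        for i, c in enumerate(sample_cols):
            a = _presence(r1[c])
            b = _presence(r2[c])
            if a == "conflict" or b == "conflict":
                n_conflict += 1
                calls[i, j] = MISSING
            elif a is None or b is None or (a, b) == (0, 0):
                calls[i, j] = MISSING  # neither allele scored
            elif (a, b) == (1, 0):
                calls[i, j] = 0
            elif (a, b) == (1, 1):
                calls[i, j] = 1
            else:  # (0, 1)
                calls[i, j] = 2
    if n_conflict:
        logger.warning("%s: %d conflicting two-row score pairs set missing", path, n_conflict)
    repro, call_rate = _dart_meta(df, meta_cols)
    return GenotypeMatrix(sample_cols, locus_ids, calls, repro, call_rate)


def _presence(v):
    if pd.isna(v) or str(v).strip() in ("", "-", "NA", "."):
        return None
    try:
        x = int(str(v).strip())
    except ValueError:
        return "conflict"
    return x if x in (0, 1) else "conflict"


def write_genotypes_vcf(gm: GenotypeMatrix, path: str | Path, contig: str = "1") -> None:
    """Write a minimal diploid VCF v4.2 (one record per locus, REF=A, ALT=T)."""
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.sample_ids) + "\n")
        for j, lid in enumerate(gm.locus_ids):
            gts = "\t".join(code[int(c)] for c in gm.calls[:, j])
            fh.write(f"{contig}\t{j + 1}\t{lid}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def write_genotypes_dart_csv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the one-row 0/1/2 DArT-style CSV (loci as rows)."""
    data = {"locus_id": gm.locus_ids}
    if gm.reproducibility is not None:
        data["reproducibility"] = gm.reproducibility
    if gm.call_rate is not None:
        data["call_rate"] = gm.call_rate
    for i, sid in enumerate(gm.sample_ids):
        data[sid] = ["-" if c == MISSING else str(int(c)) for c in gm.calls[i]]
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Sample metadata and species traits
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ["sample_id", "species_id", "site_code", "latitude", "longitude", "region_label"]


def validate_metadata(meta: pd.DataFrame, sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise GenodataError(f"metadata lacks columns {missing_cols}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise GenodataError(f"duplicate metadata rows for samples {dups}")
    lat, lon = meta["latitude"], meta["longitude"]
    if ((lat < -90) | (lat > 90)).any() or ((lon < -180) | (lon > 180)).any():
        raise GenodataError("latitude/longitude outside valid ranges")
    if sample_ids is not None:
        absent = set(sample_ids) - set(meta["sample_id"])
        if absent:
            raise GenodataError(f"samples without metadata: {sorted(absent)}")
    return meta


def read_metadata(path: str | Path, sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path), sample_ids)


@dataclass(frozen=True)
class SpeciesTraits:
    """Dispersal-relevant traits of a study species.

    ``fruit_size_class`` is derived from the maximum fruit width (large iff
    >= 30 mm); an explicit override is allowed for the occasional species
    whose published classification overrules the raw maximum width (fruit
    with thin flesh or records from inviable fruit).
    """

    species_id: str
    max_fruit_width_mm: float
    dispersal_class: str  # "fleshy" | "wind"
    indigenous_use: bool
    fruit_size_override: str | None = None

    def __post_init__(self) -> None:
        if self.max_fruit_width_mm <= 0:
            raise GenodataError("max_fruit_width_mm must be positive")
        if self.dispersal_class not in ("fleshy", "wind"):
            raise GenodataError(f"dispersal_class must be 'fleshy' or 'wind', got {self.dispersal_class!r}")
        if self.fruit_size_override not in (None, "large", "small"):
            raise GenodataError("fruit_size_override must be 'large', 'small' or None")

    @property
    def fruit_size_class(self) -> str:
        if self.fruit_size_override is not None:
            return self.fruit_size_override
        return "large" if self.max_fruit_width_mm >= LARGE_FRUIT_MIN_WIDTH_MM else "small"

    @property
    def trait_group(self) -> str:
        """One of the five fruit-trait screening groups."""
        if self.dispersal_class == "wind":
            return "wind"
        g = f"{self.fruit_size_class}_fleshy"
        return g + "_used" if self.indigenous_use else g


def read_traits(path: str | Path) -> dict[str, SpeciesTraits]:
    df = pd.read_csv(path)
    out = {}
    for _, r in df.iterrows():
        out[r["species_id"]] = SpeciesTraits(
            species_id=r["species_id"],
            max_fruit_width_mm=float(r["max_fruit_width_mm"]),
            dispersal_class=r["dispersal_class"],
            indigenous_use=bool(r["indigenous_use"]),
            fruit_size_override=r.get("fruit_size_override")
            if isinstance(r.get("fruit_size_override"), str)
            else None,
        )
    return out


# ---------------------------------------------------------------------------
# Chloroplast variant table
# ---------------------------------------------------------------------------

ANNOTATIONS = ("noncoding", "coding_synonymous", "coding_nonsynonymous")


@dataclass
class CpVariantTable:
    """Chloroplast variants with per-sample coverage and consensus support.

    ``calls`` holds allele indices (``-1`` missing), ``coverage`` read
    depths and ``consensus`` the fraction of reads supporting the call,
    all shaped ``(n_variants, n_samples)``.
    """

    positions: np.ndarray  # 1-based on the reference
    alleles: list[tuple[str, ...]]
    annotation: list[str]
    sample_ids: list[str]
    calls: np.ndarray
    coverage: np.ndarray
    consensus: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        n_v, n_s = len(self.positions), len(self.sample_ids)
        for name in ("calls", "coverage", "consensus"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n_v, n_s):
                raise GenodataError(f"{name} shape {arr.shape} != ({n_v}, {n_s})")
            setattr(self, name, arr)
        if (self.coverage < 0).any():
            raise GenodataError("negative coverage")
        if ((self.consensus < 0) | (self.consensus > 1)).any():
            raise GenodataError("consensus outside [0, 1]")
        bad = set(self.annotation) - set(ANNOTATIONS)
        if bad:
            raise GenodataError(f"unknown annotation values {sorted(bad)}")

    @property
    def n_variants(self) -> int:
        return len(self.positions)

    def subset(self, keep: np.ndarray) -> "CpVariantTable":
        idx = np.flatnonzero(keep) if np.asarray(keep).dtype == bool else np.asarray(keep)
        return CpVariantTable(
            positions=self.positions[idx],
            alleles=[self.alleles[i] for i in idx],
            annotation=[self.annotation[i] for i in idx],
            sample_ids=list(self.sample_ids),
            calls=self.calls[idx],
            coverage=self.coverage[idx],
            consensus=self.consensus[idx],
        )


@dataclass
class CpFilterReport:
    n_input: int
    n_removed_nonsynonymous: int
    n_calls_masked: int
    n_kept: int


def filter_cp_variants(
    tbl: CpVariantTable,
    min_coverage: int = 8,
    min_consensus: float = 0.60,
    drop_nonsynonymous: bool = True,
    aggregate: str = "per_sample",
) -> tuple[CpVariantTable, CpFilterReport]:
    """Apply the chloroplast variant QC rules.

    Per-sample calls with coverage below ``min_coverage`` or read consensus
    below ``min_consensus`` are set to missing (boundary values retained:
    the filters are strict ``< 8`` and ``< 60%``).  Variants annotated as
    non-synonymous in coding regions are removed entirely, as putative
    sequencing or mapping errors.  ``aggregate="per_variant"`` instead
    drops a whole variant whenever its mean coverage or mean consensus
    falls below the thresholds.
    """
    if drop_nonsynonymous and not all(a in ANNOTATIONS for a in tbl.annotation):
        raise GenodataError("annotation required to drop non-synonymous variants")
    keep = np.array([a != "coding_nonsynonymous" for a in tbl.annotation]) if drop_nonsynonymous \
        else np.ones(tbl.n_variants, dtype=bool)
    n_nonsyn = int((~keep).sum())
    out = tbl.subset(keep)
    if aggregate == "per_sample":
        mask = (out.coverage < min_coverage) | (out.consensus < min_consensus)
        calls = out.calls.copy()
        n_masked = int((mask & (calls != MISSING)).sum())
        calls[mask] = MISSING
        out = CpVariantTable(out.positions, out.alleles, out.annotation,
                             out.sample_ids, calls, out.coverage, out.consensus)
    elif aggregate == "per_variant":
        ok = (out.coverage.mean(axis=1) >= min_coverage) & (out.consensus.mean(axis=1) >= min_consensus)
        n_masked = int((~ok).sum())
        out = out.subset(ok)
    else:
        raise GenodataError(f"unknown aggregate mode {aggregate!r}")
    if out.n_variants == 0:
        raise EmptyResultError("chloroplast variant filter removed every variant")
    return out, CpFilterReport(tbl.n_variants, n_nonsyn, n_masked, out.n_variants)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

#: Characters treated as missing/ambiguous in alignment columns.
AMBIGUOUS = frozenset("NRYSWKMBDHV?-nryswkmbdhv.")


@dataclass
class Alignment:
    """Equal-length haploid sequences (e.g. a chloroplast alignment)."""

    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise GenodataError("id/sequence count mismatch")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            counts = pd.Series([len(s) for s in self.sequences], index=self.ids)
            modal = counts.mode().iloc[0]
            ragged = counts.index[counts != modal].tolist()
            raise GenodataError(f"ragged alignment; offending ids: {ragged}")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def ambiguous_columns(self) -> np.ndarray:
        """0-based indices of columns containing a gap or ambiguity code."""
        arr = np.array([list(s) for s in self.sequences])
        return np.flatnonzero(np.isin(arr, list(AMBIGUOUS)).any(axis=0))


def read_alignment(path: str | Path) -> Alignment:
    with _open_text(path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise GenodataError(f"{path}: no FASTA records")
    return Alignment(ids=[r.id for r in records], sequences=[str(r.seq) for r in records])


def write_alignment(aln: Alignment, path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.ids, aln.sequences)]
    SeqIO.write(records, str(path), "fasta")
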