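"""Domain types, table readers/writers and preprocessing filters.

All genomic intervals are stored 0-based half-open internally; readers
convert from the declared input dialect and writers convert back.  A SNP
keeps its 1-based position; its point interval is ``[pos-1, pos)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

AUTOSOMES = frozenset(str(i) for i in range(1, 23))

GENOTYPES = frozenset({"G/G", "G/A", "A/A"})


class ConfigurationError(ValueError):
    """A caller-supplied configuration (dialect, thresholds) is invalid."""


class DataError(ValueError):
    """Input data violates a contract (empty file, bad genotype, ...)."""


class MalformedRecordError(DataError):
    """A single record violates an invariant; carries the line number."""

    def __init__(self, message: str, line_no: int | None = None):
        super().__init__(message)
        self.line_no = line_no


def normalise_chrom(label: object) -> str:
    """Strip a ``chr`` prefix and return the bare chromosome label."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class SnpRecord:
    """One GWAS variant with its summary statistics.

    ``pos`` is the 1-based base position as printed in summary-statistic
    files. ``maf`` is the minor allele frequency in (0, 0.5]; readers fold
    tested-allele frequencies to the minor allele. ``liftover_ok`` is False
    for variants whose genome-version remapping was ambiguous; such
    variants are dropped by :func:`preprocess_snps`.
    """

    rsid: str
    chrom: str
    pos: int
    pvalue: float
    beta: float | None = None
    maf: float | None = None
    stratum: str | None = None
    liftover_ok: bool = True

    def __post_init__(self):
        if self.pos < 1:
            raise MalformedRecordError(f"{self.rsid}: pos must be >= 1, got {self.pos}")
        if not (0.0 < self.pvalue <= 1.0):
            raise MalformedRecordError(f"{self.rsid}: P-value {self.pvalue} outside (0, 1]")
        if self.maf is not None and not (0.0 < self.maf <= 0.5):
            raise MalformedRecordError(f"{self.rsid}: MAF {self.maf} outside (0, 0.5]")

    @property
    def pos0(self) -> int:
        """0-based position (start of the point interval)."""
        return self.pos - 1


@dataclass(frozen=True, slots=True)
class CircRnaLocus:
    """Genomic span of a circRNA between its predicted backsplice ends.

    Stored 0-based half-open ``[start, end)``; ``n_evidence`` counts the
    cell lines / tissues in which the circRNA was detected.
    """

    circ_id: str
    chrom: str
    start: int
    end: int
    n_evidence: int = 1
    source_db: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise MalformedRecordError(
                f"{self.circ_id}: start {self.start} >= end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_pos(self, pos_1based: int) -> bool:
        return self.start <= pos_1based - 1 < self.end


@dataclass(frozen=True, slots=True)
class HighLdRegion:
    """A published region of high linkage disequilibrium (0-based half-open)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise MalformedRecordError(f"LD region start {self.start} >= end {self.end}")


@dataclass(frozen=True, slots=True)
class MirnaTargetSite:
    """One miRNA target site linked to a circRNA (0-based half-open)."""

    mirna_id: str
    circ_id: str
    chrom: str
    site_start: int
    site_end: int

    def __post_init__(self):
        if self.site_start >= self.site_end:
            raise MalformedRecordError(
                f"{self.mirna_id}/{self.circ_id}: site_start >= site_end"
            )


@dataclass(frozen=True, slots=True)
class AllelicTriplicate:
    """One primer-extension replicate: A/G peak ratios on circRNA cDNA and gDNA."""

    subject_id: str
    genotype: str
    replicate: int
    ag_circ: float
    ag_gdna: float

    def __post_init__(self):
        if self.genotype not in GENOTYPES:
            raise DataError(
                f"subject {self.subject_id}: unknown genotype {self.genotype!r} "
                f"(expected one of {sorted(GENOTYPES)})"
            )
        if self.ag_circ <= 0 or self.ag_gdna <= 0:
            raise DataError(
                f"subject {self.subject_id} replicate {self.replicate}: "
                "A/G ratios must be positive"
            )


# ---------------------------------------------------------------------------
# dialects
# ---------------------------------------------------------------------------

@dataclass
class GwasDialect:
    """Column mapping for a whitespace/tab-delimited GWAS summary table."""

    chrom: str = "CHR"
    pos: str = "POS"
    rsid: str = "SNP"
    pvalue: str = "P"
    beta: str | None = "BETA"
    maf: str | None = "Freq_Tested_Allele"
    stratum: str | None = None
    liftover: str | None = None
    default_stratum: str | None = None
    sep: str = r"\s+"

    @property
    def mandatory(self) -> dict[str, str]:
        return {"chrom": self.chrom, "pos": self.pos, "rsid": self.rsid, "pvalue": self.pvalue}


@dataclass
class CircDialect:
    """How a circRNA database dump encodes coordinates and columns.

    ``coords`` is ``"onebased_closed"`` (database-style printed spans
    ``[s, e]``, converted to ``[s-1, e)``) or ``"bed0"`` (already 0-based
    half-open). ``bed0`` input is headerless BED3+ with the circRNA id in
    column 4.
    """

    coords: str = "onebased_closed"
    sep: str = "\t"
    id_col: str = "id"
    chrom_col: str = "chrom"
    start_col: str = "start"
    end_col: str = "end"
    evidence_col: str | None = "n_evidence"
    source_db: str = ""

    def __post_init__(self):
        if self.coords not in ("onebased_closed", "bed0"):
            raise ConfigurationError(f"unknown coords dialect {self.coords!r}")


@dataclass
class ReadReport:
    """Per-file audit of rows read, skipped and why."""

    n_rows: int = 0
    n_parsed: int = 0
    n_skipped: int = 0
    skipped_lines: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _opt_float(raw) -> float | None:
    """Parse an optional numeric field; NA/NaN/unparsable become None."""
    try:
        if pd.isna(raw):
            return None
        v = float(raw)
    except (TypeError, ValueError):
        return None
    return None if v != v else v


def _read_table(path, sep, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=sep, dtype=str, **kw)
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: empty input file") from None


def read_gwas_table(
    path: str | Path, dialect: GwasDialect | None = None
) -> tuple[list[SnpRecord], ReadReport]:
    """Read a GWAS summary-statistics table into :class:`SnpRecord` objects.

    Rows whose chromosome, position or P-value cannot be parsed are skipped
    and counted in the returned :class:`ReadReport`; a missing mandatory
    column raises :class:`ConfigurationError` naming it.
    """
    dialect = dialect or GwasDialect()
    df = _read_table(path, dialect.sep)
    for role, col in dialect.mandatory.items():
        if col not in df.columns:
            raise ConfigurationError(f"{path}: missing mandatory column {col!r} ({role})")

    report = ReadReport(n_rows=len(df))
    records: list[SnpRecord] = []
    has = df.columns.__contains__
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        row = dict(zip(df.columns, row))
        try:
            chrom = normalise_chrom(row[dialect.chrom])
            pos = int(float(row[dialect.pos]))
            pvalue = float(row[dialect.pvalue])
            beta = None
            if dialect.beta and has(dialect.beta):
                beta = _opt_float(row[dialect.beta])
            maf = None
            if dialect.maf and has(dialect.maf):
                f = _opt_float(row[dialect.maf])
                if f is not None and 0.0 < f < 1.0:
                    maf = min(f, 1.0 - f)
            stratum = dialect.default_stratum
            if dialect.stratum and has(dialect.stratum):
                raw = row[dialect.stratum]
                if not pd.isna(raw) and str(raw) != "NA":
                    stratum = str(raw)
            liftover_ok = True
            if dialect.liftover and has(dialect.liftover):
                liftover_ok = str(row[dialect.liftover]).strip().lower() in (
                    "1", "true", "ok", "yes",
                )
            records.append(
                SnpRecord(
                    rsid=str(row[dialect.rsid]),
                    chrom=chrom,
                    pos=pos,
                    pvalue=pvalue,
                    beta=beta,
                    maf=maf,
                    stratum=stratum,
                    liftover_ok=liftover_ok,
                )
            )
        except (TypeError, ValueError):
            report.n_skipped += 1
            report.skipped_lines.append(i)
    report.n_parsed = len(records)
    return records, report


def read_circ_table(
    path: str | Path, dialect: CircDialect | None = None
) -> list[CircRnaLocus]:
    """Read a circRNA database dump, normalising coordinates to 0-based half-open."""
    dialect = dialect or CircDialect()
    if dialect.coords == "bed0":
        df = _read_table(path, dialect.sep, header=None)
        if df.shape[1] < 4:
            raise ConfigurationError(f"{path}: bed0 dialect needs >= 4 columns")
        cols = {0: dialect.chrom_col, 1: dialect.start_col, 2: dialect.end_col, 3: dialect.id_col}
        df = df.rename(columns=cols)
        evid_col = 4 if df.shape[1] > 4 else None
        offset = 0
        first_line = 1
    else:
        df = _read_table(path, dialect.sep)
        for col in (dialect.id_col, dialect.chrom_col, dialect.start_col, dialect.end_col):
            if col not in df.columns:
                raise ConfigurationError(f"{path}: missing column {col!r}")
        evid_col = (
            dialect.evidence_col if dialect.evidence_col in df.columns else None
        )
        offset = 1  # printed [s, e] -> [s-1, e)
        first_line = 2

    loci: list[CircRnaLocus] = []
    for i, row in enumerate(df.to_dict("records"), start=first_line):
        start = int(float(row[dialect.start_col])) - offset
        end = int(float(row[dialect.end_col]))
        if end <= start:
            raise MalformedRecordError(
                f"{path} line {i}: end {end} <= start {start} after conversion",
                line_no=i,
            )
        n_evidence = 1
        if evid_col is not None and not pd.isna(row[evid_col]):
            n_evidence = int(float(row[evid_col]))
        loci.append(
            CircRnaLocus(
                circ_id=str(row[dialect.id_col]),
                chrom=normalise_chrom(row[dialect.chrom_col]),
                start=start,
                end=end,
                n_evidence=n_evidence,
                source_db=dialect.source_db,
            )
        )
    return loci


def read_ld_regions(path: str | Path) -> list[HighLdRegion]:
    """Read a BED3 file of published high-LD regions."""
    df = _read_table(path, r"\s+", header=None)
    return [
        HighLdRegion(normalise_chrom(r[0]), int(float(r[1])), int(float(r[2])))
        for r in df.itertuples(index=False)
    ]


def read_mirna_sites(path: str | Path) -> list[MirnaTargetSite]:
    """Read a TSV of miRNA target sites (mirna_id, circ_id, chrom, start, end)."""
    df = _read_table(path, "\t")
    needed = ["mirna_id", "circ_id", "chrom", "start", "end"]
    for col in needed:
        if col not in df.columns:
            raise ConfigurationError(f"{path}: missing column {col!r}")
    return [
        MirnaTargetSite(
            mirna_id=str(r["mirna_id"]),
            circ_id=str(r["circ_id"]),
            chrom=normalise_chrom(r["chrom"]),
            site_start=int(float(r["start"])),
            site_end=int(float(r["end"])),
        )
        for r in df.to_dict("records")
    ]


def read_allelic_table(path: str | Path) -> list[AllelicTriplicate]:
    """Read the allelic primer-extension CSV, validating the genotype vocabulary."""
    df = _read_table(path, ",")
    needed = ["subject_id", "genotype", "replicate", "ag_circ", "ag_gdna"]
    for col in needed:
        if col not in df.columns:
            raise ConfigurationError(f"{path}: missing column {col!r}")
    out: list[AllelicTriplicate] = []
    for i, r in enumerate(df.to_dict("records"), start=2):
        geno = str(r["genotype"]).strip()
        if geno not in GENOTYPES:
            raise DataError(
                f"{path} line {i}: subject {r['subject_id']}: unknown genotype {geno!r}"
            )
        out.append(
            AllelicTriplicate(
                subject_id=str(r["subject_id"]),
                genotype=geno,
                replicate=int(float(r["replicate"])),
                ag_circ=float(r["ag_circ"]),
                ag_gdna=float(r["ag_gdna"]),
            )
        )
    # group rows by subject to keep replicates adjacent
    out.sort(key=lambda t: (t.subject_id, t.replicate))
    return out


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers above)
# ---------------------------------------------------------------------------

def write_gwas_table(snps: Sequence[SnpRecord], path: str | Path,
                     dialect: GwasDialect | None = None) -> None:
    dialect = dialect or GwasDialect()
    cols = {
        dialect.chrom: [s.chrom for s in snps],
        dialect.pos: [s.pos for s in snps],
        dialect.rsid: [s.rsid for s in snps],
        dialect.pvalue: [repr(s.pvalue) for s in snps],
    }
    # "NA" placeholders keep whitespace-delimited columns aligned
    if dialect.beta:
        cols[dialect.beta] = [("NA" if s.beta is None else repr(s.beta)) for s in snps]
    if dialect.maf:
        cols[dialect.maf] = [("NA" if s.maf is None else repr(s.maf)) for s in snps]
    if dialect.stratum:
        cols[dialect.stratum] = [s.stratum or "NA" for s in snps]
    if dialect.liftover:
        cols[dialect.liftover] = [int(s.liftover_ok) for s in snps]
    sep = "\t" if dialect.sep == r"\s+" else dialect.sep
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)


def write_circ_table(loci: Sequence[CircRnaLocus], path: str | Path,
                     dialect: CircDialect | None = None) -> None:
    dialect = dialect or CircDialect()
    if dialect.coords == "bed0":
        df = pd.DataFrame(
            {
                0: [c.chrom for c in loci],
                1: [c.start for c in loci],
                2: [c.end for c in loci],
                3: [c.circ_id for c in loci],
                4: [c.n_evidence for c in loci],
            }
        )
        df.to_csv(path, sep=dialect.sep, index=False, header=False)
    else:
        df = pd.DataFrame(
            {
                dialect.id_col: [c.circ_id for c in loci],
                dialect.chrom_col: [c.chrom for c in loci],
                dialect.start_col: [c.start + 1 for c in loci],
                dialect.end_col: [c.end for c in loci],
                dialect.evidence_col or "n_evidence": [c.n_evidence for c in loci],
            }
        )
        df.to_csv(path, sep=dialect.sep, index=False)


def write_ld_regions(regions: Sequence[HighLdRegion], path: str | Path) -> None:
    pd.DataFrame(
        {0: [r.chrom for r in regions], 1: [r.start for r in regions], 2: [r.end for r in regions]}
    ).to_csv(path, sep="\t", index=False, header=False)


def write_mirna_sites(sites: Sequence[MirnaTargetSite], path: str | Path) -> None:
    pd.DataFrame(
        {
            "mirna_id": [s.mirna_id for s in sites],
            "circ_id": [s.circ_id for s in sites],
            "chrom": [s.chrom for s in sites],
            "start": [s.site_start for s in sites],
            "end": [s.site_end for s in sites],
        }
    ).to_csv(path, sep="\t", index=False)


def write_allelic_table(trips: Sequence[AllelicTriplicate], path: str | Path) -> None:
    pd.DataFrame(
        {
            "subject_id": [t.subject_id for t in trips],
            "genotype": [t.genotype for t in trips],
            "replicate": [t.replicate for t in trips],
            "ag_circ": [repr(t.ag_circ) for t in trips],
            "ag_gdna": [repr(t.ag_gdna) for t in trips],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# preprocessing filters
# ---------------------------------------------------------------------------

@dataclass
class PreprocessReport:
    n_input: int = 0
    sex_removed: int = 0
    duplicates_removed: int = 0
    liftover_removed: int = 0
    n_retained: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def preprocess_circ(
    loci: Iterable[CircRnaLocus], autosomes: frozenset[str] = AUTOSOMES
) -> tuple[list[CircRnaLocus], PreprocessReport]:
    """Drop sex-chromosome loci and collapse within-database duplicates.

    A duplicate is a repeated ``circ_id`` or a repeated ``(chrom, start,
    end)`` span within one source database; the first occurrence is kept.
    """
    loci = list(loci)
    report = PreprocessReport(n_input=len(loci))
    kept: list[CircRnaLocus] = []
    seen_ids: set[tuple[str, str]] = set()
    seen_spans: set[tuple[str, str, int, int]] = set()
    for c in loci:
        if c.chrom not in autosomes:
            report.sex_removed += 1
            continue
        id_key = (c.source_db, c.circ_id)
        span_key = (c.source_db, c.chrom, c.start, c.end)
        if id_key in seen_ids or span_key in seen_spans:
            report.duplicates_removed += 1
            continue
        seen_ids.add(id_key)
        seen_spans.add(span_key)
        kept.append(c)
    report.n_retained = len(kept)
    return kept, report


def preprocess_snps(
    snps: Iterable[SnpRecord], autosomes: frozenset[str] = AUTOSOMES
) -> tuple[list[SnpRecord], PreprocessReport]:
    """Drop ambiguously remapped variants, duplicate rsids and sex-chromosome SNPs."""
    snps = list(snps)
    report = PreprocessReport(n_input=len(snps))
    kept: list[SnpRecord] = []
    seen: set[str] = set()
    for s in snps:
        if not s.liftover_ok:
            report.liftover_removed += 1
            continue
        if s.chrom not in autosomes:
            report.sex_removed += 1
            continue
        if s.rsid in seen:
            report.duplicates_removed += 1
            continue
        seen.add(s.rsid)
        kept.append(s)
    report.n_retained = len(kept)
    return kept, report
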