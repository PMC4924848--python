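"""Reading, writing and packaged fixtures for GWAS summary-statistic tables.

GWAS consortia publish per-SNP association results in delimited text with
wildly inconsistent headers.  This module normalizes any such table into a
list of :class:`SummaryRecord` through an explicit ``column_map`` — columns
are never guessed, because silently misread effect columns are the dominant
failure mode of summary-data Mendelian randomization.

It also ships the packaged example dataset: the 70 BMI-associated SNPs
(genome-wide significant in the GIANT European sex-combined analysis) with
their multiple-sclerosis odds ratios from the IMSGC Immunochip and
IMSGC/WTCCC2 studies, including the proxy-SNP bookkeeping (36 proxies with
UK10K r-squared, 34 directly genotyped).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

from mr2s.errors import ConfigError, ValidationError

log = logging.getLogger("mr2s.summary_io")

#: Fields of SummaryRecord that read_summary_table can populate from columns.
_NUMERIC_FIELDS = ("eaf", "beta", "or_", "ci_low", "ci_high", "se", "pvalue")
_STRING_FIELDS = ("snp_id", "chrom", "effect_allele", "other_allele")

FIXTURE_RESOURCE = "bmi_ms_instruments.tsv"


@dataclass
class SummaryRecord:
    """One SNP's association with one trait, as reported by a GWAS.

    Effect sizes may arrive as a beta with SE (continuous traits, SD units)
    or as an odds ratio with a 95% CI (binary traits); at least one of the
    two must be present.  Missing values are ``None``, never zero.
    """

    snp_id: str
    chrom: Optional[str] = None
    effect_allele: Optional[str] = None
    other_allele: Optional[str] = None
    eaf: Optional[float] = None
    beta: Optional[float] = None
    or_: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    se: Optional[float] = None
    pvalue: Optional[float] = None
    trait: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.beta is None and self.or_ is None:
            raise ValidationError(f"{self.snp_id}: neither beta nor OR present")
        if self.or_ is not None:
            if self.or_ <= 0:
                raise ValidationError(f"{self.snp_id}: OR must be positive, got {self.or_}")
            if self.ci_low is not None and self.ci_high is not None:
                # <= rather than <: printed tables round the OR onto a bound
                if not self.ci_low <= self.or_ <= self.ci_high:
                    raise ValidationError(
                        f"{self.snp_id}: CI ({self.ci_low}, {self.ci_high}) does not bracket OR {self.or_}"
                    )
        if self.se is not None and self.se <= 0:
            raise ValidationError(f"{self.snp_id}: SE must be positive, got {self.se}")
        if self.eaf is not None and not 0.0 <= self.eaf <= 1.0:
            raise ValidationError(f"{self.snp_id}: EAF {self.eaf} outside [0, 1]")
        if self.pvalue is not None and not 0.0 < self.pvalue <= 1.0:
            raise ValidationError(f"{self.snp_id}: p-value {self.pvalue} outside (0, 1]")


@dataclass
class Fixture:
    """The packaged 70-SNP BMI/MS instrument table.

    ``proxy_map`` has one entry per SNP: ``snp_id -> (proxy_id, r2, source)``.
    For directly genotyped SNPs the proxy id equals the SNP's own id and
    r2 is 1.0.  Note that proxy status is *not* ``r2 < 1`` — the r-squared
    values are printed to two decimals, so a handful of genuine proxies
    round to 1.00.
    """

    exposure_records: list[SummaryRecord]
    outcome_records: list[SummaryRecord]
    proxy_map: dict[str, tuple[str, float, str]]

    @property
    def proxied_ids(self) -> list[str]:
        """SNPs whose outcome effect comes from a distinct proxy variant."""
        return [s for s, (p, _, _) in self.proxy_map.items() if p != s]

    @property
    def n_proxies(self) -> int:
        return len(self.proxied_ids)

    @property
    def mean_proxy_r2(self) -> float:
        r2s = [self.proxy_map[s][1] for s in self.proxied_ids]
        return sum(r2s) / len(r2s)


def _parse_float(cell: str) -> Optional[float]:
    """Parse a numeric cell; unparseable or empty cells become missing."""
    cell = cell.strip()
    if cell in ("", "NA", "na", "NaN", "nan", ".", "-"):
        return None
    try:
        return float(cell)
    except ValueError:
        return None


def _sniff_delimiter(header_line: str, delimiter: Optional[str]) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if "\t" in header_line else ","


def read_summary_table(
    path: str | Path,
    column_map: Mapping[str, str],
    trait: str = "",
    source: str = "",
    delimiter: Optional[str] = None,
    source_column: Optional[str] = None,
) -> list[SummaryRecord]:
    """Read a delimited summary-statistics table into SummaryRecords.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Maps record field names (``snp_id``, ``beta``, ``or_``, ``se``,
        ``ci_low``, ``ci_high``, ``eaf``, ``pvalue``, ``chrom``,
        ``effect_allele``, ``other_allele``) to column names in the file.
        ``snp_id`` plus at least one of ``beta``/``or_`` are mandatory.
    trait, source
        Labels stamped on every record.
    source_column
        Optional column holding a per-row source label (overrides ``source``).

    Row order is preserved; unparseable numeric cells become missing,
    never zero.
    """
    path = Path(path)
    known = set(_NUMERIC_FIELDS) | set(_STRING_FIELDS)
    unknown = set(column_map) - known
    if unknown:
        raise ConfigError(f"column_map has unknown field(s): {sorted(unknown)}")
    if "snp_id" not in column_map:
        raise ConfigError("column_map must map the mandatory field 'snp_id'")
    if "beta" not in column_map and "or_" not in column_map:
        raise ConfigError("column_map must map at least one effect column ('beta' or 'or_')")

    with path.open(newline="") as fh:
        first = fh.readline()
        if not first:
            raise ValidationError(f"{path}: empty file")
        delim = _sniff_delimiter(first, delimiter)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        wanted = list(column_map.values()) + ([source_column] if source_column else [])
        missing = [c for c in wanted if c not in header]
        if missing:
            raise ConfigError(f"{path}: missing mandatory column(s): {missing}")
        records: list[SummaryRecord] = []
        for row in reader:
            kwargs: dict = {"trait": trait, "source": source}
            for fld in _STRING_FIELDS:
                if fld in column_map:
                    val = (row[column_map[fld]] or "").strip()
                    kwargs[fld] = val if val and val.upper() != "NA" else None
            for fld in _NUMERIC_FIELDS:
                if fld in column_map:
                    kwargs[fld] = _parse_float(row[column_map[fld]] or "")
            if source_column:
                kwargs["source"] = (row[source_column] or "").strip()
            if not kwargs.get("snp_id"):
                raise ValidationError(f"{path}: row with empty snp_id")
            records.append(SummaryRecord(**kwargs))

    dupes = _duplicates([r.snp_id for r in records])
    if dupes:
        raise ValidationError(f"{path}: duplicate snp_id(s): {dupes}")
    log.info("read %d summary records from %s (trait=%s)", len(records), path, trait)
    return records


def write_summary_table(records: Sequence[SummaryRecord], path: str | Path, delimiter: str = "\t") -> None:
    """Write records to a delimited file that :func:`read_summary_table`
    round-trips bit-identically (floats via ``repr``, missing as NA)."""
    path = Path(path)
    cols = [f.name for f in fields(SummaryRecord)]
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(cols)
        for rec in records:
            row = []
            for c in cols:
                v = getattr(rec, c)
                if v is None:
                    row.append("NA")
                elif isinstance(v, float):
                    row.append(repr(v))
                else:
                    row.append(str(v))
            writer.writerow(row)


def identity_column_map() -> dict[str, str]:
    """Column map for files written by :func:`write_summary_table`."""
    return {f: f for f in _STRING_FIELDS + _NUMERIC_FIELDS}


def _duplicates(ids: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dup: list[str] = []
    for i in ids:
        if i in seen and i not in dup:
            dup.append(i)
        seen.add(i)
    return dup


def fixture_path() -> Path:
    """Filesystem path of the packaged instrument table."""
    return Path(str(resources.files("mr2s").joinpath("data", FIXTURE_RESOURCE)))


def load_fixture() -> Fixture:
    """Load the packaged 70-SNP BMI/MS instrument table.

    Exposure records carry the per-allele effect on BMI (SD units) and its
    GIANT p-value, oriented to the BMI-increasing allele (the other allele
    is not printed, so harmonization runs in ``pre_oriented`` mode).
    Outcome records carry the MS odds ratio with its 95% CI and source
    study.  The proxy map records, for each SNP, which variant actually
    supplied the outcome association and the UK10K r-squared between them.
    """
    path = fixture_path()
    exposure: list[SummaryRecord] = []
    outcome: list[SummaryRecord] = []
    proxy_map: dict[str, tuple[str, float, str]] = {}
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            snp = row["snp_id"]
            exposure.append(
                SummaryRecord(
                    snp_id=snp,
                    chrom=row["chrom"],
                    effect_allele=row["effect_allele"],
                    eaf=float(row["eaf"]),
                    beta=float(row["beta_bmi"]),
                    pvalue=float(row["pvalue_bmi"]),
                    trait="BMI",
                    source="GIANT",
                )
            )
            outcome.append(
                SummaryRecord(
                    snp_id=snp,
                    chrom=row["chrom"],
                    effect_allele=row["effect_allele"],
                    or_=float(row["or_ms"]),
                    ci_low=float(row["ci_low_ms"]),
                    ci_high=float(row["ci_high_ms"]),
                    pvalue=float(row["pvalue_ms"]),
                    trait="MS",
                    source=row["source"],
                )
            )
            proxy = row["proxy_id"]
            proxy_map[snp] = (
                snp if proxy == "NA" else proxy,
                float(row["proxy_r2"]),
                row["source"],
            )
    fx = Fixture(exposure, outcome, proxy_map)
    assert len(fx.exposure_records) == 70, "packaged table must have 70 rows"
    assert fx.n_proxies == 36, "packaged table must have 36 proxied SNPs"
    return fx
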