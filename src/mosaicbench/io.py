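"""Domain types and file I/O for the mosaic-variant evidence database.

The evidence database holds, per candidate SNV, the somatic caller's
annotations plus ref/alt read counts from each sequencing technology
(Illumina discovery data and the orthogonal BGI, Element and PacBio HiFi
datasets), and genomic-context flags derived from stratification BEDs.

Coordinate conventions: everything in memory is 0-based half-open (BED
native); conversion from/to 1-based VCF positions happens only at the I/O
boundary.  ``VariantKey.pos`` is the 1-based VCF position, the one exception,
because variant identity is conventionally written that way
(e.g. "chr10:106867519"); use :meth:`VariantKey.pos0` for interval work.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

_BASES = frozenset("ACGT")


class Technology(enum.Enum):
    ILLUMINA = "ILLUMINA"
    BGI = "BGI"
    ELEMENT = "ELEMENT"
    HIFI = "HIFI"


class ContextFlag(enum.Enum):
    EASY_TO_MAP = "EASY_TO_MAP"
    HOMOPOLYMER = "HOMOPOLYMER"
    TANDEM_REPEAT = "TANDEM_REPEAT"
    OVERLAPS_GERMLINE_INDEL = "OVERLAPS_GERMLINE_INDEL"
    IN_COMPLEX_OR_SV = "IN_COMPLEX_OR_SV"


class Verdict(enum.Enum):
    KEEP = "KEEP"
    REMOVE = "REMOVE"
    UNCERTAIN = "UNCERTAIN"


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a single-nucleotide variant (1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (1-based), got {self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"ref/alt must be single bases in ACGT, got {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")

    @property
    def pos0(self) -> int:
        """0-based position (the BED interval is [pos0, pos0 + 1))."""
        return self.pos - 1

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class TechReadSupport:
    """Ref/alt read counts for one variant from one technology."""

    technology: Technology
    ref_count: int
    alt_count: int
    depth: int

    def __post_init__(self) -> None:
        if min(self.ref_count, self.alt_count, self.depth) < 0:
            raise ValueError("read counts must be non-negative")
        if self.ref_count + self.alt_count > self.depth:
            raise ValueError(
                f"ref_count + alt_count ({self.ref_count}+{self.alt_count}) exceeds depth {self.depth}"
            )


@dataclass
class VariantEvidence:
    """One candidate SNV with caller annotations and multi-tech read support."""

    key: VariantKey
    supports: list[TechReadSupport] = field(default_factory=list)
    caller_filter: str = "PASS"
    tar_depth: int = 0
    flags: set[ContextFlag] = field(default_factory=set)

    def __post_init__(self) -> None:
        techs = [s.technology for s in self.supports]
        if len(techs) != len(set(techs)):
            raise ValueError(f"duplicate technology in supports for {self.key}")

    def support_for(self, tech: Technology) -> TechReadSupport | None:
        for s in self.supports:
            if s.technology is tech:
                return s
        return None


@dataclass(frozen=True)
class CurationLabel:
    """Manual-curation verdict for one candidate variant."""

    key: VariantKey
    verdict: Verdict
    note: str = ""


@dataclass(frozen=True)
class SnvRecord:
    """A single SNV read from a callset VCF."""

    key: VariantKey
    caller_filter: str = "PASS"
    tar_depth: int | None = None
    vaf: float | None = None


class MalformedInputError(ValueError):
    """Raised when an input file violates its declared dialect."""


# ---------------------------------------------------------------------------
# evidence table (bam-readcount-style TSV)
# ---------------------------------------------------------------------------

EVIDENCE_COLUMNS = ("chrom", "pos", "ref", "alt", "technology", "ref_count", "alt_count", "depth")

#: curation verdict spellings accepted on input; "?" is the sheet shorthand
_VERDICT_ALIASES = {"KEEP": Verdict.KEEP, "REMOVE": Verdict.REMOVE, "?": Verdict.UNCERTAIN,
                    "UNCERTAIN": Verdict.UNCERTAIN}


def read_evidence_table(path: str | Path, schema: dict[str, str] | None = None) -> list[VariantEvidence]:
    """Read a per-variant, per-technology read-count TSV into evidence records.

    Each row carries one (variant, technology) pair; rows sharing a variant
    key are grouped into a single :class:`VariantEvidence`.  ``schema``
    optionally maps the required logical column names to the file's column
    names.  Optional columns ``caller_filter`` and ``tar_depth`` are picked
    up per variant when present.
    """
    path = Path(path)
    colmap = {c: c for c in EVIDENCE_COLUMNS}
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in EVIDENCE_COLUMNS if colmap[c] not in df.columns]
    if missing:
        raise MalformedInputError(f"{path}: missing required columns {missing}")

    grouped: dict[VariantKey, VariantEvidence] = {}
    seen: set[tuple[VariantKey, Technology]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 is the header
        r = row._asdict()
        try:
            key = VariantKey(
                chrom=r[colmap["chrom"]],
                pos=int(r[colmap["pos"]]),
                ref=r[colmap["ref"]].upper(),
                alt=r[colmap["alt"]].upper(),
            )
            tech = Technology(r[colmap["technology"]].upper())
            support = TechReadSupport(
                technology=tech,
                ref_count=int(r[colmap["ref_count"]]),
                alt_count=int(r[colmap["alt_count"]]),
                depth=int(r[colmap["depth"]]),
            )
        except (KeyError, ValueError) as exc:
            raise MalformedInputError(f"{path}, line {i}: {exc}") from exc
        if (key, tech) in seen:
            raise MalformedInputError(f"{path}, line {i}: duplicate entry for ({key}, {tech.value})")
        seen.add((key, tech))
        ev = grouped.get(key)
        if ev is None:
            ev = VariantEvidence(key=key, supports=[])
            if "caller_filter" in df.columns:
                ev.caller_filter = r["caller_filter"]
            if "tar_depth" in df.columns:
                ev.tar_depth = int(r["tar_depth"])
            grouped[key] = ev
        ev.supports.append(support)
    return list(grouped.values())


def write_evidence_table(evidences: Iterable[VariantEvidence], path: str | Path) -> None:
    rows = []
    for ev in evidences:
        for s in ev.supports:
            rows.append(
                dict(chrom=ev.key.chrom, pos=ev.key.pos, ref=ev.key.ref, alt=ev.key.alt,
                     technology=s.technology.value, ref_count=s.ref_count,
                     alt_count=s.alt_count, depth=s.depth,
                     caller_filter=ev.caller_filter, tar_depth=ev.tar_depth)
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file as-is (0-based half-open; no sorting, no merging).

    Returns a DataFrame with columns chrom/start/end plus any extra columns
    (named bed4, bed5, ...).  Raw fidelity is preserved so write(read(f))
    round-trips; use :meth:`mosaicbench.regions.IntervalSet.from_dataframe`
    to normalize for interval algebra.
    """
    path = Path(path)
    rows = []
    n_extra = 0
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise MalformedInputError(f"{path}, line {i}: BED needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise MalformedInputError(f"{path}, line {i}: non-integer coordinates") from exc
            if end <= start:
                raise MalformedInputError(f"{path}, line {i}: end {end} <= start {start}")
            if start < 0:
                raise MalformedInputError(f"{path}, line {i}: negative start")
            rows.append([parts[0], start, end, *parts[3:]])
            n_extra = max(n_extra, len(parts) - 3)
    cols = ["chrom", "start", "end"] + [f"bed{i + 4}" for i in range(n_extra)]
    df = pd.DataFrame(rows, columns=cols[: 3 + n_extra] if rows else cols)
    if df.empty:
        df = pd.DataFrame(columns=["chrom", "start", "end"])
    return df


def write_bed(intervals, path: str | Path) -> None:
    """Write BED3+ from a DataFrame (chrom/start/end[/...]) or an IntervalSet."""
    if hasattr(intervals, "to_dataframe"):
        intervals = intervals.to_dataframe()
    with open(path, "w") as fh:
        for row in intervals.itertuples(index=False):
            fh.write("\t".join(str(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _info_get(rec, key):
    # pysam raises on INFO keys absent from the header; treat as missing
    try:
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def read_snv_vcf(
    path: str | Path,
    sample: str | None = None,
    require: Sequence[str] = (),
) -> tuple[list[SnvRecord], int]:
    """Read SNVs from a VCF; returns (snv_records, n_indels_excluded).

    Indels and MNVs are excluded from the SNV list and tallied.  Multi-allelic
    records are rejected (normalize/split upstream, e.g. ``bcftools norm -m-``).
    ``require`` lists annotations ("tar_depth", "vaf") that must be present on
    every SNV record; absence raises :class:`MalformedInputError`.

    The caller filter string is read from FILTER verbatim (e.g. the
    "VARIANT_DETECTED_IN_NORMAL" token used to drop variants seen in the
    normal sample), tar_depth from INFO/TAR or FORMAT/TAR, and vaf from
    INFO/VAF or FORMAT/VAF (or FORMAT/AF).
    """
    path = str(path)
    records: list[SnvRecord] = []
    n_indels = 0
    with pysam.VariantFile(path) as vcf:
        sample_names = list(vcf.header.samples)
        if sample is not None and sample not in sample_names:
            raise MalformedInputError(f"{path}: sample {sample!r} not in VCF samples {sample_names}")
        use_sample = sample or (sample_names[0] if sample_names else None)
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) > 1:
                raise MalformedInputError(
                    f"{path}: multi-allelic record at {rec.chrom}:{rec.pos}; "
                    "normalize with 'bcftools norm -m-' before loading"
                )
            if not alts:
                continue
            ref, alt = rec.ref, alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                n_indels += 1
                continue
            filt = ";".join(rec.filter.keys()) or "PASS"
            tar = _info_get(rec, "TAR")
            vaf = _info_get(rec, "VAF")
            if use_sample is not None:
                fmt = rec.samples[use_sample]
                if tar is None and "TAR" in fmt:
                    tar = fmt["TAR"]
                if vaf is None:
                    vaf = fmt.get("VAF", fmt.get("AF"))
            if isinstance(tar, tuple):
                tar = tar[0]  # tier-1 count
            if isinstance(vaf, tuple):
                vaf = vaf[0]
            missing = [name for name, val in (("tar_depth", tar), ("vaf", vaf))
                       if name in require and val is None]
            if missing:
                raise MalformedInputError(
                    f"{path}: record {rec.chrom}:{rec.pos} lacks required annotation(s) {missing}"
                )
            records.append(
                SnvRecord(
                    key=VariantKey(rec.chrom, rec.pos, ref, alt),
                    caller_filter=filt,
                    tar_depth=int(tar) if tar is not None else None,
                    vaf=float(vaf) if vaf is not None else None,
                )
            )
    return records, n_indels


def write_benchmark_vcf(
    records: Iterable[tuple[VariantKey, float]],
    path: str | Path,
    contigs: dict[str, int] | None = None,
    sample: str = "HG002",
) -> None:
    """Write benchmark SNVs as a VCF 4.2 with INFO/VAF and a 0/1 genotype.

    ``records`` is an iterable of (key, vaf).  ``contigs`` maps contig name to
    length; when omitted, contig lines are emitted without lengths.
    """
    records = sorted(records, key=lambda r: (r[0].chrom, r[0].pos, r[0].alt))
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction from combined read support">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    names = contigs or {k.chrom: None for k, _ in records}
    for name, length in names.items():
        if length:
            header.add_line(f"##contig=<ID={name},length={length}>")
        else:
            header.add_line(f"##contig=<ID={name}>")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for key, vaf in records:
            rec = out.new_record(
                contig=key.chrom, start=key.pos0, stop=key.pos,
                alleles=(key.ref, key.alt), filter="PASS",
            )
            rec.info["VAF"] = float(vaf)
            rec.samples[sample]["GT"] = (0, 1)
            out.write(rec)


# ---------------------------------------------------------------------------
# curation labels
# ---------------------------------------------------------------------------

def read_curation_csv(path: str | Path) -> list[CurationLabel]:
    """Read a curation sheet CSV with columns chrom,pos,ref,alt,verdict[,note]."""
    path = Path(path)
    labels: list[CurationLabel] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        needed = {"chrom", "pos", "ref", "alt", "verdict"}
        if reader.fieldnames is None or not needed <= set(reader.fieldnames):
            raise MalformedInputError(f"{path}: curation CSV needs columns {sorted(needed)}")
        for i, row in enumerate(reader, start=2):
            verdict = _VERDICT_ALIASES.get(row["verdict"].strip().upper() or "?")
            if verdict is None:
                raise MalformedInputError(f"{path}, line {i}: unknown verdict {row['verdict']!r}")
            try:
                key = VariantKey(row["chrom"], int(row["pos"]), row["ref"].upper(), row["alt"].upper())
            except ValueError as exc:
                raise MalformedInputError(f"{path}, line {i}: {exc}") from exc
            labels.append(CurationLabel(key=key, verdict=verdict, note=row.get("note", "")))
    return labels


def write_curation_csv(labels: Iterable[CurationLabel], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["chrom", "pos", "ref", "alt", "verdict", "note"])
        for lab in labels:
            writer.writerow([lab.key.chrom, lab.key.pos, lab.key.ref, lab.key.alt,
                             lab.verdict.value, lab.note])
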