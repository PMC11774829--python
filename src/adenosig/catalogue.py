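"""Somatic call intake and 96-channel substitution catalogues.

This module turns per-caller VCFs into consensus, quality-filtered mutation
records, classifies SNVs into the 96 canonical trinucleotide substitution
classes (pyrimidine-centred, COSMIC row order) against a reference genome,
and computes tumour mutation burden (TMB) over a capture region.

Conventions
-----------
* Coordinates are 1-based, as in VCF; the trinucleotide context is the
  closed window ``[pos-1, pos+1]``.
* When the reference base of an SNV is a purine, the substitution and both
  flanking bases are reverse-complemented so the central base is a
  pyrimidine (``G>T`` in an ``AGA`` context becomes ``T[C>A]T``).
* Consensus calling keeps variants whose ``(chrom, pos, ref, alt)`` key is
  reported by both callers; depth and VAF are taken from the first caller's
  record and caller labels are unioned.
* Depth/VAF filters are inclusive: ``depth >= min_depth`` and
  ``vaf >= min_vaf`` are kept.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .errors import (
    ConfigurationError,
    ContextUnavailableError,
    ReferenceMismatchError,
)

logger = logging.getLogger(__name__)

SUBSTITUTIONS: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: The 96 canonical substitution classes in COSMIC row order: substitution
#: type major, then 5' flank, then 3' flank, each in A/C/G/T order.
CLASSES_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

_CLASS_INDEX = {c: i for i, c in enumerate(CLASSES_96)}

#: The 32 pyrimidine-centred trinucleotide contexts.
CONTEXTS_32: tuple[str, ...] = tuple(
    sorted({f"{five}{central}{three}" for five in BASES for central in "CT" for three in BASES})
)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def classify_alleles(ref: str, alt: str) -> str:
    """Assign a variant type from REF/ALT allele lengths.

    Returns one of ``SNV``, ``INS``, ``DEL``, ``MNV``.
    """
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(ref) < len(alt):
        return "INS"
    if len(ref) > len(alt):
        return "DEL"
    return "MNV"


@dataclass
class MutationRecord:
    """One somatic call with depth/VAF and caller provenance."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    var_type: str
    depth: int
    vaf: float
    callers: frozenset[str]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        expected = classify_alleles(self.ref, self.alt)
        if self.var_type != expected:
            raise ValueError(
                f"var_type {self.var_type!r} inconsistent with alleles "
                f"{self.ref}>{self.alt} (expected {expected!r})"
            )
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf out of [0,1]: {self.vaf}")
        if self.depth < 0:
            raise ValueError(f"negative depth: {self.depth}")
        if not self.callers:
            raise ValueError("callers set is empty")
        self.callers = frozenset(self.callers)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class Catalogue96:
    """Per-sample counts over the 96 canonical substitution classes."""

    sample_id: str
    counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CLASSES_96})
    indel_total: int = 0

    def __post_init__(self) -> None:
        if set(self.counts) != set(CLASSES_96):
            missing = set(CLASSES_96) - set(self.counts)
            extra = set(self.counts) - set(CLASSES_96)
            raise ValueError(
                f"counts keys must be the 96 canonical classes "
                f"(missing {len(missing)}, unexpected {len(extra)})"
            )
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative class count")
        if self.indel_total < 0:
            raise ValueError("negative indel_total")
        # normalise key order to the canonical one
        self.counts = {c: int(self.counts[c]) for c in CLASSES_96}

    @property
    def snv_total(self) -> int:
        return sum(self.counts.values())

    def as_array(self):
        import numpy as np

        return np.array([self.counts[c] for c in CLASSES_96], dtype=float)


@dataclass(frozen=True)
class TmbResult:
    """Tumour mutation burden over a capture region."""

    tmb: float
    capture_mb: float
    hypermutated: bool


def _depth_vaf_for_alt(rec, alt_index: int, sample_name: str | None):
    """Derive (depth, vaf) for one ALT allele of a VCF row.

    Preference order: per-sample AD (+DP); per-sample DP+AF; INFO DP+AF.
    Returns None when nothing derivable.
    """
    samples = rec.samples
    if len(samples) > 0:
        name = sample_name if sample_name is not None else list(samples)[0]
        fmt = samples[name]
        ad = fmt.get("AD")
        if ad is not None and None not in tuple(ad):
            ad = tuple(int(x) for x in ad)
            depth = fmt.get("DP")
            depth = int(depth) if depth is not None else sum(ad)
            if depth > 0 and alt_index + 1 < len(ad):
                return depth, ad[alt_index + 1] / depth
        dp = fmt.get("DP")
        af = fmt.get("AF")
        if dp is not None and af is not None:
            af = af[alt_index] if isinstance(af, tuple) else af
            if af is not None:
                return int(dp), float(af)
    try:  # pysam raises on INFO keys absent from the header
        dp = rec.info.get("DP")
        af = rec.info.get("AF")
    except ValueError:
        return None
    if dp is not None and af is not None:
        af = af[alt_index] if isinstance(af, tuple) else af
        return int(dp), float(af)
    return None


def read_somatic_vcf(
    path: str | Path,
    sample_id: str,
    caller: str,
    vcf_sample: str | None = None,
) -> list[MutationRecord]:
    """Read somatic calls from one caller's VCF.

    Emits one :class:`MutationRecord` per ALT allele of each PASS (or
    unfiltered) row. Depth and VAF come from the genotype AD field when
    present, else DP+AF (FORMAT or INFO). Rows with no derivable depth/VAF
    are excluded with a logged warning rather than silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[MutationRecord] = []
    n_flagged = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            filters = list(rec.filter.keys())
            if filters and filters != ["PASS"]:
                continue
            if rec.alts is None:
                continue
            for alt_index, alt in enumerate(rec.alts):
                derived = _depth_vaf_for_alt(rec, alt_index, vcf_sample)
                if derived is None:
                    n_flagged += 1
                    logger.warning(
                        "%s:%d %s>%s in %s: no derivable depth/VAF, excluded",
                        rec.chrom, rec.pos, rec.ref, alt, path.name,
                    )
                    continue
                depth, vaf = derived
                records.append(
                    MutationRecord(
                        sample_id=sample_id,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        var_type=classify_alleles(rec.ref, alt),
                        depth=depth,
                        vaf=min(max(vaf, 0.0), 1.0),
                        callers=frozenset({caller}),
                    )
                )
    if n_flagged:
        logger.warning("%s: %d allele(s) excluded for missing depth/VAF", path.name, n_flagged)
    return records


def intersect_callers(
    calls_a: Sequence[MutationRecord], calls_b: Sequence[MutationRecord]
) -> list[MutationRecord]:
    """Consensus of two callers' call sets for one sample.

    Keeps records whose ``(chrom, pos, ref, alt)`` key appears in both
    inputs. Numeric evidence (depth, VAF) is taken from the first caller's
    record; caller labels are unioned. Order follows ``calls_a``.
    """
    keys_b: dict[tuple, frozenset[str]] = {}
    for r in calls_b:
        keys_b[r.key] = keys_b.get(r.key, frozenset()) | r.callers
    out: list[MutationRecord] = []
    seen: set[tuple] = set()
    for r in calls_a:
        if r.key in keys_b and r.key not in seen:
            seen.add(r.key)
            out.append(replace(r, callers=r.callers | keys_b[r.key]))
    return out


def filter_records(
    records: Sequence[MutationRecord],
    min_depth: int = 50,
    min_vaf: float = 0.10,
) -> list[MutationRecord]:
    """Apply inclusive depth and VAF thresholds, preserving order."""
    if min_depth < 0 or min_vaf < 0:
        raise ConfigurationError("filter thresholds must be non-negative")
    return [r for r in records if r.depth >= min_depth and r.vaf >= min_vaf]


def _context_triplet(reference, chrom: str, pos: int) -> str:
    """Extract the reference bases at [pos-1, pos+1] (1-based, inclusive)."""
    if pos < 2:
        raise ContextUnavailableError(f"{chrom}:{pos} has no 5' flank")
    try:
        seq = reference[chrom]
    except KeyError as exc:
        raise ContextUnavailableError(f"contig {chrom!r} not in reference") from exc
    window = seq[pos - 2 : pos + 1]
    ctx = str(window).upper()
    if len(ctx) != 3:
        raise ContextUnavailableError(f"{chrom}:{pos} has no 3' flank")
    return ctx


def trinucleotide_class(record: MutationRecord, reference) -> str:
    """Classify an SNV into one of the 96 canonical substitution classes.

    ``reference`` is any mapping from contig name to a sliceable sequence
    (a ``pyfaidx.Fasta`` or a plain dict of strings).
    """
    if record.var_type != "SNV":
        raise ValueError(f"trinucleotide_class requires an SNV, got {record.var_type}")
    ctx = _context_triplet(reference, record.chrom, record.pos)
    if ctx[1] != record.ref.upper():
        raise ReferenceMismatchError(
            f"{record.chrom}:{record.pos}: reference base {ctx[1]} != REF {record.ref}"
        )
    ref, alt = record.ref.upper(), record.alt.upper()
    if ref in "AG":  # purine: flip to the pyrimidine strand
        ctx = revcomp(ctx)
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    label = f"{ctx[0]}[{ref}>{alt}]{ctx[2]}"
    if label not in _CLASS_INDEX:
        raise ValueError(f"unclassifiable context {ctx!r} for {record.chrom}:{record.pos}")
    return label


def build_catalogue(
    records: Sequence[MutationRecord],
    reference,
    sample_id: str | None = None,
) -> Catalogue96:
    """Count filtered records into a 96-class catalogue plus indel total.

    Only SNVs enter the 96 channels; INS/DEL records are tallied in
    ``indel_total``; MNVs are excluded from both with a logged count.
    Contig-edge SNVs (no flank) are excluded with a warning.
    """
    if sample_id is None:
        sample_id = records[0].sample_id if records else "sample"
    counts: Counter[str] = Counter()
    indel_total = 0
    n_mnv = 0
    n_edge = 0
    for rec in records:
        if rec.var_type in ("INS", "DEL"):
            indel_total += 1
        elif rec.var_type == "MNV":
            n_mnv += 1
        else:
            try:
                counts[trinucleotide_class(rec, reference)] += 1
            except ContextUnavailableError as exc:
                n_edge += 1
                logger.warning("excluding contig-edge SNV: %s", exc)
    if n_mnv:
        logger.info("%s: %d MNV record(s) excluded from catalogue and TMB", sample_id, n_mnv)
    if n_edge:
        logger.warning("%s: %d contig-edge SNV(s) excluded", sample_id, n_edge)
    full = {c: counts.get(c, 0) for c in CLASSES_96}
    return Catalogue96(sample_id=sample_id, counts=full, indel_total=indel_total)


def compute_tmb(
    catalogue: Catalogue96,
    capture_mb: float = 67.0,
    hypermutation_threshold: float = 10.0,
) -> TmbResult:
    """Mutations (SNVs + indels) per megabase of capture region."""
    if capture_mb <= 0:
        raise ConfigurationError(f"capture_mb must be positive, got {capture_mb}")
    tmb = (catalogue.snv_total + catalogue.indel_total) / capture_mb
    return TmbResult(tmb=tmb, capture_mb=capture_mb, hypermutated=tmb >= hypermutation_threshold)


def catalogue_frame(catalogues: Iterable[Catalogue96]) -> pd.DataFrame:
    """Wide per-sample catalogue table: one row per sample, 96 class columns."""
    rows = []
    for cat in catalogues:
        row: dict = {"sample_id": cat.sample_id}
        row.update(cat.counts)
        row["snv_total"] = cat.snv_total
        row["indel_total"] = cat.indel_total
        rows.append(row)
    return pd.DataFrame(rows)


def write_catalogue_tsv(catalogue: Catalogue96, path: str | Path) -> None:
    """Per-sample catalogue TSV: 96 rows {class, count} in canonical order."""
    pd.DataFrame(
        {"class": CLASSES_96, "count": [catalogue.counts[c] for c in CLASSES_96]}
    ).to_csv(path, sep="\t", index=False)


def write_burden_tsv(
    results: Mapping[str, tuple[Catalogue96, TmbResult]], path: str | Path
) -> None:
    """Per-sample burden TSV {sample_id, snv_total, indel_total, tmb, hypermutated}."""
    rows = [
        {
            "sample_id": sid,
            "snv_total": cat.snv_total,
            "indel_total": cat.indel_total,
            "tmb": tmb.tmb,
            "hypermutated": tmb.hypermutated,
        }
        for sid, (cat, tmb) in results.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
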