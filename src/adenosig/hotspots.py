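"""Recurrent hotspot flagging and 2x2 diagnostic performance.

Two recurrent somatic changes act as biomarkers of biallelic MUTYH status
in colorectal tumours: KRAS c.34G>T p.(Gly12Cys) and PIK3CA c.1636C>A
p.(Gln546Lys). Matching is by exact genomic key (chrom, pos, ref, alt) on
a named reference build — deterministic and annotation-free. Diagnostic
performance against case/control status is summarised as a 2x2 table with
PPV, NPV, sensitivity and specificity, plus association p-values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from scipy import stats

from .catalogue import MutationRecord
from .errors import ConfigurationError
from .formatting import round_half_up

GenomicKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class HotspotDef:
    """One hotspot: HGVS description plus per-build genomic keys."""

    gene: str
    transcript: str
    hgvs_c: str
    hgvs_p: str
    keys: Mapping[str, GenomicKey] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for build, (chrom, pos, ref, alt) in self.keys.items():
            if len(ref) != 1 or len(alt) != 1 or ref == alt:
                raise ValueError(
                    f"{self.name} [{build}]: genomic key must describe an SNV"
                )
        object.__setattr__(self, "keys", dict(self.keys))

    @property
    def name(self) -> str:
        return f"{self.gene}_{self.hgvs_c}"

    def key_for(self, build: str) -> GenomicKey:
        if build not in self.keys:
            raise ConfigurationError(
                f"hotspot {self.name} has no genomic key for build {build!r}"
            )
        return self.keys[build]


# Coordinates shipped for convenience; verify against your annotation source
# before clinical use. KRAS is on the minus strand, so c.34G>T is a genomic
# C>A; PIK3CA is on the plus strand.
DEFAULT_REGISTRY: tuple[HotspotDef, ...] = (
    HotspotDef(
        gene="KRAS",
        transcript="NM_001369786.1",
        hgvs_c="c.34G>T",
        hgvs_p="p.(Gly12Cys)",
        keys={
            "GRCh37": ("12", 25398285, "C", "A"),
            "GRCh38": ("12", 25245351, "C", "A"),
        },
    ),
    HotspotDef(
        gene="PIK3CA",
        transcript="NM_006218.4",
        hgvs_c="c.1636C>A",
        hgvs_p="p.(Gln546Lys)",
        keys={
            "GRCh37": ("3", 178936094, "C", "A"),
            "GRCh38": ("3", 179218306, "C", "A"),
        },
    ),
)


def load_registry(path: str | Path) -> list[HotspotDef]:
    """Load a hotspot registry from JSON.

    Expected layout: a list of objects with gene/transcript/hgvs_c/hgvs_p
    and a ``keys`` object mapping build name to [chrom, pos, ref, alt].
    """
    with open(path) as fh:
        raw = json.load(fh)
    out = []
    for entry in raw:
        keys = {b: (k[0], int(k[1]), k[2], k[3]) for b, k in entry["keys"].items()}
        out.append(
            HotspotDef(
                gene=entry["gene"],
                transcript=entry.get("transcript", ""),
                hgvs_c=entry["hgvs_c"],
                hgvs_p=entry.get("hgvs_p", ""),
                keys=keys,
            )
        )
    return out


def write_registry(registry: Sequence[HotspotDef], path: str | Path) -> None:
    payload = [
        {
            "gene": h.gene,
            "transcript": h.transcript,
            "hgvs_c": h.hgvs_c,
            "hgvs_p": h.hgvs_p,
            "keys": {b: list(k) for b, k in h.keys.items()},
        }
        for h in registry
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def match_hotspots(
    records: Sequence[MutationRecord],
    registry: Sequence[HotspotDef],
    build: str,
) -> dict[str, bool]:
    """Flag, per hotspot, whether any record matches its genomic key exactly."""
    present = {r.key for r in records}
    return {h.name: h.key_for(build) in present for h in registry}


@dataclass(frozen=True)
class Diagnostic2x2:
    """2x2 diagnostic table of a binary flag against case status.

    ``ppv``/``npv``/``sensitivity``/``specificity`` are percentages at full
    precision, ``None`` when the defining denominator is zero; use
    :meth:`as_report` for the one-decimal presentation.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("2x2 counts must be non-negative")
        if self.tp + self.fp + self.fn + self.tn == 0:
            raise ValueError("2x2 table is empty")

    @property
    def ppv(self) -> float | None:
        d = self.tp + self.fp
        return 100.0 * self.tp / d if d else None

    @property
    def npv(self) -> float | None:
        d = self.tn + self.fn
        return 100.0 * self.tn / d if d else None

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return 100.0 * self.tn / d if d else None

    def as_report(self) -> dict[str, float | int | None]:
        """Counts plus percentages rounded half-up to one decimal."""
        rounded = {
            k: (round_half_up(v, 1) if v is not None else None)
            for k, v in (
                ("ppv", self.ppv),
                ("npv", self.npv),
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
            )
        }
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn, **rounded}


def diagnostic_2x2(
    case_flags: Sequence[bool], control_flags: Sequence[bool]
) -> Diagnostic2x2:
    """Build the 2x2 table from per-sample flags in cases and controls."""
    return Diagnostic2x2(
        tp=sum(bool(f) for f in case_flags),
        fn=sum(not f for f in case_flags),
        fp=sum(bool(f) for f in control_flags),
        tn=sum(not f for f in control_flags),
    )


def hotspot_association_test(table: Diagnostic2x2) -> dict[str, float]:
    """Association p-values for flag vs case status.

    Reports both Fisher's exact test (two-sided) on the 2x2 table and a
    two-sided Welch t-test on the 0/1 indicators. Both are given because
    neither can be singled out as *the* canonical choice for small
    case-control tables; read them together.
    """
    from .cohort_stats import welch_t_test

    _, fisher_p = stats.fisher_exact(
        [[table.tp, table.fp], [table.fn, table.tn]], alternative="two-sided"
    )
    cases = [1.0] * table.tp + [0.0] * table.fn
    controls = [1.0] * table.fp + [0.0] * table.tn
    if len(cases) < 2 or len(controls) < 2:
        ttest_p = float("nan")
    else:
        try:
            _, _, ttest_p = welch_t_test(cases, controls)
        except ZeroDivisionError:
            ttest_p = float("nan")
    return {"fisher_p": float(fisher_p), "ttest_p": float(ttest_p)}
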