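"""Synthetic cohorts with known ground truth.

The study groups this generator emulates are colorectal adenomas and
cancers from people with biallelic MUTYH or NTHL1 loss, mismatch-repair
(MMR) deficient MUTYH cancers, and non-hereditary controls. Each group is
described by a :class:`GroupProfile`: a mean signature-exposure vector
(MUTYH-like dominated by SBS18/SBS36, NTHL1-like by SBS30, controls by
clock-like SBS1/SBS5, MMR-deficient adding SBS15/SBS44 with inflated
burden), Dirichlet concentration calibrated to the published group
dispersions, log-normal SNV/indel burden distributions calibrated to the
published group means and SDs, sequencing depth and VAF distributions,
and group-dependent hotspot prevalences.

For each sample the generator draws a true exposure vector, draws class
counts from the implied 96-channel multinomial, places every SNV at a
reference position whose trinucleotide context matches its class, and
emits two caller VCFs that share all true calls plus per-caller private
false calls at a configurable discordance rate — so the consensus
pipeline can be validated against construction-time truth.

The bundled 16-signature reference matrix is a SYNTHETIC stand-in built
programmatically: its signatures carry COSMIC-style names and
qualitatively right context preferences (SBS18/SBS36 C>A-heavy, SBS30
C>T-heavy, SBS1 C>T at CpG, ...) but are not the COSMIC v3 vectors.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pyfaidx

from .catalogue import BASES, CLASSES_96, COMPLEMENT, CONTEXTS_32, revcomp
from .errors import ConfigurationError
from .hotspots import HotspotDef
from .refit import SignatureMatrix, write_signature_tsv

logger = logging.getLogger(__name__)

SYNTHETIC_BUILD = "synthetic"

DEFAULT_SIGNATURE_NAMES: tuple[str, ...] = (
    "SBS1", "SBS2", "SBS3", "SBS5", "SBS10a", "SBS13", "SBS15", "SBS17b",
    "SBS18", "SBS28", "SBS30", "SBS36", "SBS40", "SBS41", "SBS44", "SBS93",
)

# Channel-preference recipes for the synthetic stand-in signatures:
# (substitution, 5' flank or None, 3' flank or None) masks, OR'd together.
# Flat entries get a broad tilt instead of sharp peaks so that the
# clock-like signatures remain mutually identifiable.
_RECIPES: dict[str, list[tuple[str, str | None, str | None]]] = {
    "SBS1": [("C>T", None, "G")],
    "SBS2": [("C>T", "T", None)],
    "SBS3": [],  # near-flat
    "SBS5": [("T>C", None, None)],  # broad, T>C tilted
    "SBS10a": [("C>A", "T", "T")],
    "SBS13": [("C>G", "T", None)],
    "SBS15": [("C>T", "G", None)],
    "SBS17b": [("T>G", "C", "T")],
    "SBS18": [("C>A", None, "A"), ("C>A", None, "T")],
    "SBS28": [("T>G", None, None)],
    "SBS30": [("C>T", None, "A"), ("C>T", None, "C"), ("C>T", None, "T")],
    "SBS36": [("C>A", None, "C"), ("C>A", None, "G")],
    "SBS40": [("C>A", None, None), ("T>A", None, None)],  # broad
    "SBS41": [("T>A", None, None)],
    "SBS44": [("C>T", "C", "T"), ("T>C", None, "T")],
    "SBS93": [("T>C", "A", None), ("T>C", "T", None)],
}
_BROAD = {"SBS3", "SBS5", "SBS40"}


def _channel_mask(specs: list[tuple[str, str | None, str | None]]) -> np.ndarray:
    mask = np.zeros(96, dtype=bool)
    for sub, five, three in specs:
        for i, cls in enumerate(CLASSES_96):
            if cls[2:5] != sub:
                continue
            if five is not None and cls[0] != five:
                continue
            if three is not None and cls[6] != three:
                continue
            mask[i] = True
    return mask


def synthetic_signature_matrix(
    names: Sequence[str] = DEFAULT_SIGNATURE_NAMES, seed: int = 7
) -> SignatureMatrix:
    """Deterministic synthetic stand-in for a 16-signature reference set.

    Each signature concentrates most of its mass (85 %, or 55 % for the
    broad clock-like ones) on its recipe's channels, with seeded Dirichlet
    weights inside the peak set and a uniform background elsewhere.
    """
    rng = np.random.default_rng(seed)
    cols = []
    for name in names:
        if name not in _RECIPES:
            raise KeyError(f"no recipe for signature {name!r}")
        mask = _channel_mask(_RECIPES[name])
        peak_mass = 0.55 if name in _BROAD else 0.85
        col = np.full(96, (1.0 - peak_mass) / 96)
        if mask.sum() == 0:  # fully flat recipe
            col = rng.dirichlet(np.full(96, 60.0))
        else:
            col[~mask] = (1.0 - peak_mass) / 96
            peak = rng.dirichlet(np.full(int(mask.sum()), 3.0)) * (
                1.0 - (1.0 - peak_mass) / 96 * (~mask).sum()
            )
            col[mask] = peak
        cols.append(col / col.sum())
    return SignatureMatrix(tuple(names), np.column_stack(cols))


@dataclass(frozen=True)
class GroupProfile:
    """The stated world for one cohort group."""

    label: str
    n_samples: int
    exposure_mean: Mapping[str, float]
    exposure_concentration: float  # total Dirichlet concentration
    snv_count: tuple[float, float]  # natural-scale (mean, sd), log-normal
    indel_count: tuple[float, float]
    hotspot_rates: Mapping[str, float] = field(default_factory=dict)
    depth_mean: float = 357.9
    vaf_beta: tuple[float, float] = (7.0, 13.0)  # mean 0.35
    contamination: float = 0.05  # fraction of true calls forced below filters
    discordance: float = 0.10  # per-caller private false-call rate
    tissue: str = "adenoma"
    mmr_status: str = "proficient"

    def __post_init__(self) -> None:
        total = sum(self.exposure_mean.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigurationError(
                f"{self.label}: exposure_mean sums to {total}, expected 1"
            )
        if self.n_samples < 0:
            raise ConfigurationError("n_samples must be >= 0")
        for r in self.hotspot_rates.values():
            if not 0 <= r <= 1:
                raise ConfigurationError("hotspot rates must be in [0, 1]")
        if not 0 <= self.contamination <= 1 or not 0 <= self.discordance <= 1:
            raise ConfigurationError("contamination/discordance must be in [0, 1]")

    def mean_vector(self, names: Sequence[str]) -> np.ndarray:
        v = np.array([self.exposure_mean.get(n, 0.0) for n in names])
        unnamed = set(self.exposure_mean) - set(names)
        if unnamed:
            raise ConfigurationError(f"{self.label}: unknown signatures {unnamed}")
        return v


@dataclass(frozen=True)
class TruthRecord:
    """Construction-time ground truth for one simulated sample."""

    sample_id: str
    true_exposures: Mapping[str, float]
    true_snv_count: int
    true_indel_count: int
    true_hotspot_flags: Mapping[str, bool]


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Convert a natural-scale (mean, sd) to log-normal (mu, sigma)."""
    var = sd**2
    sigma2 = np.log1p(var / mean**2)
    mu = np.log(mean) - sigma2 / 2
    return mu, float(np.sqrt(sigma2))


# Group calibration notes: exposure_concentration is the total Dirichlet
# concentration alpha0 chosen so the marker signature's SD matches the
# published group SD via Var = p(1-p)/(alpha0+1); burden (mean, sd) pairs
# are the published group SNV/indel summaries.
def default_profiles() -> list[GroupProfile]:
    """The default seven-group colorectal cohort."""
    return [
        GroupProfile(
            label="MUTYH_adenoma",
            n_samples=9,
            exposure_mean={
                "SBS18": 0.44, "SBS36": 0.22, "SBS1": 0.10, "SBS5": 0.14,
                "SBS40": 0.05, "SBS3": 0.05,
            },
            exposure_concentration=1.6,  # marker SD ~29.6 %
            snv_count=(318.6, 285.4),
            indel_count=(4.4, 4.9),
            hotspot_rates={"KRAS_c.34G>T": 0.667, "PIK3CA_c.1636C>A": 0.0},
            tissue="adenoma",
        ),
        GroupProfile(
            label="MUTYH_CRC",
            n_samples=13,
            exposure_mean={
                "SBS18": 0.50, "SBS36": 0.262, "SBS1": 0.08, "SBS5": 0.10,
                "SBS40": 0.058,
            },
            exposure_concentration=3.3,  # marker SD ~20.5 %
            snv_count=(494.3, 197.5),
            indel_count=(9.7, 4.6),
            hotspot_rates={"KRAS_c.34G>T": 0.692, "PIK3CA_c.1636C>A": 0.25},
            tissue="CRC",
        ),
        GroupProfile(
            label="MMRd_MUTYH_CRC",
            n_samples=2,
            exposure_mean={
                "SBS15": 0.25, "SBS44": 0.25, "SBS18": 0.13, "SBS36": 0.07,
                "SBS1": 0.12, "SBS5": 0.15, "SBS40": 0.03,
            },
            exposure_concentration=10.0,
            snv_count=(2650.0, 1300.0),  # TMB well above 10 mutations/Mb
            indel_count=(40.0, 20.0),
            hotspot_rates={"KRAS_c.34G>T": 0.692},
            tissue="CRC",
            mmr_status="deficient",
        ),
        GroupProfile(
            label="NTHL1_adenoma",
            n_samples=7,
            exposure_mean={
                "SBS30": 0.745, "SBS1": 0.10, "SBS5": 0.10, "SBS40": 0.035,
                "SBS18": 0.01, "SBS36": 0.01,
            },
            exposure_concentration=20.5,  # marker SD ~9.4 %
            snv_count=(466.9, 274.5),
            indel_count=(10.7, 9.3),
            tissue="adenoma",
        ),
        GroupProfile(
            label="NTHL1_CRC",
            n_samples=2,
            exposure_mean={
                "SBS30": 0.788, "SBS1": 0.09, "SBS5": 0.09, "SBS40": 0.028,
                "SBS18": 0.004,
            },
            exposure_concentration=100.0,  # marker SD ~2.4 %
            snv_count=(491.0, 132.9),
            indel_count=(10.5, 0.7),
            tissue="CRC",
        ),
        GroupProfile(
            label="control_adenoma",
            n_samples=27,
            exposure_mean={
                "SBS18": 0.05, "SBS36": 0.03, "SBS1": 0.30, "SBS5": 0.35,
                "SBS40": 0.12, "SBS3": 0.05, "SBS30": 0.03, "SBS2": 0.02,
                "SBS13": 0.02, "SBS93": 0.03,
            },
            exposure_concentration=13.3,  # marker SD ~7.0 %
            snv_count=(91.1, 56.8),
            indel_count=(7.1, 4.2),
            hotspot_rates={"KRAS_c.34G>T": 0.074},
            tissue="adenoma",
        ),
        GroupProfile(
            label="control_CRC",
            n_samples=26,
            exposure_mean={
                "SBS18": 0.04, "SBS36": 0.025, "SBS1": 0.30, "SBS5": 0.35,
                "SBS40": 0.13, "SBS3": 0.05, "SBS30": 0.054, "SBS2": 0.02,
                "SBS13": 0.02, "SBS93": 0.011,
            },
            exposure_concentration=19.3,
            snv_count=(178.1, 86.9),
            indel_count=(11.3, 5.4),
            tissue="CRC",
        ),
    ]


def make_reference(
    out_path: str | Path,
    seed: int = 0,
    n_contigs: int = 2,
    contig_length: int = 100_000,
) -> Path:
    """Write a random FASTA reference hosting all 32 trinucleotide contexts.

    Deterministic for a given seed; builds a .fai index alongside. Raises
    when the sequence is too short to contain every pyrimidine-centred
    context.
    """
    if contig_length < 3:
        raise ConfigurationError("contig_length must be >= 3")
    rng = np.random.default_rng(seed)
    out_path = Path(out_path)
    contigs: dict[str, str] = {}
    for i in range(n_contigs):
        seq = "".join(np.array(list(BASES))[rng.integers(0, 4, size=contig_length)])
        contigs[f"chr{i + 1}"] = seq
    present = set()
    for seq in contigs.values():
        for i in range(len(seq) - 2):
            tri = seq[i : i + 3]
            present.add(tri if tri[1] in "CT" else revcomp(tri))
    missing = set(CONTEXTS_32) - present
    if missing:
        raise ConfigurationError(
            f"reference too short: {len(missing)} trinucleotide context(s) absent"
        )
    with open(out_path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for j in range(0, len(seq), 60):
                fh.write(seq[j : j + 60] + "\n")
    pyfaidx.Faidx(str(out_path))
    return out_path


def build_context_index(reference: pyfaidx.Fasta) -> dict[str, list[tuple[str, int, bool]]]:
    """Index genomic positions by pyrimidine-centred context.

    Returns, for each of the 32 contexts, a list of (chrom, 1-based pos,
    needs_revcomp) where needs_revcomp marks sites whose central base is a
    purine on the forward strand.
    """
    index: dict[str, list[tuple[str, int, bool]]] = {c: [] for c in CONTEXTS_32}
    for chrom in reference.keys():
        seq = str(reference[chrom][:]).upper()
        for i in range(1, len(seq) - 1):
            tri = seq[i - 1 : i + 2]
            if "N" in tri:
                continue
            if tri[1] in "CT":
                index[tri].append((chrom, i + 1, False))
            else:
                index[revcomp(tri)].append((chrom, i + 1, True))
    return index


def synthetic_hotspot_registry(reference: pyfaidx.Fasta) -> list[HotspotDef]:
    """Hotspot registry keyed on the synthetic build.

    Stand-in loci: the first G at/after position 1000 of the first contig
    plays the KRAS c.34G>T part (G>T), the first C at/after position 2000
    plays PIK3CA c.1636C>A (C>A). Deterministic given the reference.
    """
    chrom = list(reference.keys())[0]
    seq = str(reference[chrom][:]).upper()

    def first_base(base: str, start: int) -> int:
        for i in range(start, len(seq) - 1):
            if seq[i] == base:
                return i + 1  # 1-based
        raise ConfigurationError(f"no {base} found in {chrom} after {start}")

    kras_pos = first_base("G", 999)
    pik_pos = first_base("C", 1999)
    return [
        HotspotDef(
            gene="KRAS", transcript="NM_001369786.1",
            hgvs_c="c.34G>T", hgvs_p="p.(Gly12Cys)",
            keys={SYNTHETIC_BUILD: (chrom, kras_pos, "G", "T")},
        ),
        HotspotDef(
            gene="PIK3CA", transcript="NM_006218.4",
            hgvs_c="c.1636C>A", hgvs_p="p.(Gln546Lys)",
            keys={SYNTHETIC_BUILD: (chrom, pik_pos, "C", "A")},
        ),
    ]


def _class_to_context(cls: str) -> tuple[str, str, str]:
    """Split 'A[C>T]G' into (context 'ACG', ref 'C', alt 'T')."""
    return cls[0] + cls[2] + cls[6], cls[2], cls[4]


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=adenosig-simulator
{contigs}##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR
"""


def _write_vcf(path: Path, calls: list[tuple[str, int, str, str, int, float]],
               contig_lengths: Mapping[str, int]) -> None:
    """Write calls as a minimal single-sample VCFv4.2 with AD/DP."""
    contig_lines = "".join(
        f"##contig=<ID={name},length={length}>\n"
        for name, length in contig_lengths.items()
    )
    order = {name: i for i, name in enumerate(contig_lengths)}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contig_lines))
        for chrom, pos, ref, alt, depth, vaf in sorted(
            calls, key=lambda c: (order[c[0]], c[1], c[3])
        ):
            alt_reads = int(round(vaf * depth))
            ref_reads = depth - alt_reads
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\t"
                f"AD:DP\t{ref_reads},{alt_reads}:{depth}\n"
            )


def _draw_depth_vaf(rng, profile, n, passing=None):
    """Draw depths and VAFs; contaminated calls are forced below filters."""
    depth = np.maximum(rng.poisson(profile.depth_mean, size=n), 1)
    vaf = rng.beta(*profile.vaf_beta, size=n)
    vaf = np.clip(vaf, 0.10, 0.95)  # true calls pass unless contaminated
    if passing is None:
        passing = rng.random(n) >= profile.contamination
    fail_mode = rng.random(n) < 0.5
    for i in np.flatnonzero(~np.asarray(passing)):
        if fail_mode[i]:
            vaf[i] = rng.uniform(0.005, 0.09)
        else:
            depth[i] = rng.integers(5, 49)
    return depth, vaf, passing


def simulate_sample(
    profile: GroupProfile,
    reference: pyfaidx.Fasta,
    signatures: SignatureMatrix,
    seed: int,
    sample_id: str,
    out_dir: str | Path,
    context_index: dict | None = None,
    hotspot_registry: Sequence[HotspotDef] | None = None,
) -> tuple[Path, Path, TruthRecord]:
    """Simulate one sample: two caller VCFs plus its ground truth.

    See the module docstring for the generative model. The hotspot, when
    planted, overwrites one drawn SNV so burden totals remain as drawn,
    and always passes the depth/VAF filters.
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if context_index is None:
        context_index = build_context_index(reference)
    if hotspot_registry is None:
        hotspot_registry = synthetic_hotspot_registry(reference)
    names = signatures.names
    alpha = profile.exposure_concentration * profile.mean_vector(names)
    alpha = np.maximum(alpha, 1e-3)
    e_true = rng.dirichlet(alpha)

    mu, sig = _lognormal_params(*profile.snv_count)
    m = max(int(round(rng.lognormal(mu, sig))), 1)
    mu_i, sig_i = _lognormal_params(*profile.indel_count)
    n_indel = max(int(round(rng.lognormal(mu_i, sig_i))), 0)

    class_probs = signatures.probs @ e_true
    class_probs = class_probs / class_probs.sum()
    class_counts = rng.multinomial(m, class_probs)

    used: set[tuple[str, int]] = set()
    snvs: list[tuple[str, int, str, str]] = []  # chrom, pos, ref, alt (genomic)
    for ci in np.flatnonzero(class_counts):
        context, ref_py, alt_py = _class_to_context(CLASSES_96[ci])
        sites = context_index[context]
        if not sites:
            raise ConfigurationError(f"reference hosts no {context} context")
        need = int(class_counts[ci])
        picks = rng.choice(len(sites), size=min(need * 3 + 8, len(sites)), replace=False)
        placed = 0
        for p in picks:
            chrom, pos, flipped = sites[p]
            if (chrom, pos) in used:
                continue
            used.add((chrom, pos))
            if flipped:
                snvs.append((chrom, pos, COMPLEMENT[ref_py], COMPLEMENT[alt_py]))
            else:
                snvs.append((chrom, pos, ref_py, alt_py))
            placed += 1
            if placed == need:
                break
        if placed < need:
            logger.warning(
                "%s: placed %d/%d SNVs for class %s (reference saturated)",
                sample_id, placed, need, CLASSES_96[ci],
            )

    # hotspots overwrite drawn SNVs so the burden total stays as drawn
    hotspot_flags: dict[str, bool] = {}
    hotspot_calls: list[tuple[str, int, str, str]] = []
    for hs in hotspot_registry:
        rate = profile.hotspot_rates.get(hs.name, 0.0)
        flag = bool(rng.random() < rate)
        hotspot_flags[hs.name] = flag
        if flag:
            chrom, pos, ref, alt = hs.key_for(SYNTHETIC_BUILD)
            if snvs:
                snvs.pop(rng.integers(len(snvs)))
            hotspot_calls.append((chrom, pos, ref, alt))
            used.add((chrom, pos))

    n_true = len(snvs) + len(hotspot_calls)
    depth, vaf, _ = _draw_depth_vaf(rng, profile, len(snvs))
    true_calls = [
        (*snvs[i], int(depth[i]), float(vaf[i])) for i in range(len(snvs))
    ]
    for chrom, pos, ref, alt in hotspot_calls:
        true_calls.append((chrom, pos, ref, alt, max(int(rng.poisson(profile.depth_mean)), 50),
                           float(rng.uniform(0.2, 0.6))))

    # indels: uniform placement, 50/50 insertion vs deletion
    contig_names = list(reference.keys())
    contig_lengths = {c: len(reference[c]) for c in contig_names}
    d_i, v_i, _ = _draw_depth_vaf(rng, profile, n_indel)
    indel_calls = []
    for i in range(n_indel):
        chrom = contig_names[rng.integers(len(contig_names))]
        pos = int(rng.integers(2, contig_lengths[chrom] - 2))
        while (chrom, pos) in used:
            pos = int(rng.integers(2, contig_lengths[chrom] - 2))
        used.add((chrom, pos))
        anchor = str(reference[chrom][pos - 1 : pos + 1]).upper()
        if rng.random() < 0.5:  # deletion of one base
            ref_a, alt_a = anchor, anchor[0]
        else:  # insertion of one random base
            ref_a, alt_a = anchor[0], anchor[0] + BASES[rng.integers(4)]
        indel_calls.append((chrom, pos, ref_a, alt_a, int(d_i[i]), float(v_i[i])))

    shared = true_calls + indel_calls

    def private_calls(n_private: int) -> list:
        out = []
        for _ in range(n_private):
            chrom = contig_names[rng.integers(len(contig_names))]
            pos = int(rng.integers(2, contig_lengths[chrom] - 2))
            if (chrom, pos) in used:
                continue
            ref_b = str(reference[chrom][pos - 1]).upper()
            alt_b = BASES[(BASES.index(ref_b) + 1 + rng.integers(3)) % 4]
            out.append((chrom, pos, ref_b, alt_b,
                        max(int(rng.poisson(profile.depth_mean)), 1),
                        float(np.clip(rng.beta(*profile.vaf_beta), 0.1, 0.95))))
        return out

    n_priv = rng.binomial(max(n_true, 1), profile.discordance)
    vcf_a = out_dir / f"{sample_id}.callerA.vcf"
    vcf_b = out_dir / f"{sample_id}.callerB.vcf"
    _write_vcf(vcf_a, shared + private_calls(n_priv), contig_lengths)
    _write_vcf(vcf_b, shared + private_calls(n_priv), contig_lengths)

    truth = TruthRecord(
        sample_id=sample_id,
        true_exposures=dict(zip(names, e_true.tolist())),
        true_snv_count=n_true,
        true_indel_count=n_indel,
        true_hotspot_flags=hotspot_flags,
    )
    return vcf_a, vcf_b, truth


def simulate_cohort(
    profiles: Sequence[GroupProfile],
    out_dir: str | Path,
    seed: int = 0,
    signatures: SignatureMatrix | None = None,
    reference_path: str | Path | None = None,
    contig_length: int = 100_000,
) -> Path:
    """Simulate a full cohort directory.

    Writes: ``reference.fa`` (+index), per-sample paired caller VCFs under
    ``vcf/``, ``metadata.tsv``, ``truth.tsv``, ``signatures.tsv``,
    ``hotspots.json`` and a ``config.json`` echo. The global seed fans out
    deterministically to per-sample seeds, so the same seed reproduces the
    same directory byte for byte.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if signatures is None:
        signatures = synthetic_signature_matrix()
    if reference_path is None:
        reference_path = make_reference(out_dir / "reference.fa", seed=seed,
                                        contig_length=contig_length)
    reference = pyfaidx.Fasta(str(reference_path))
    context_index = build_context_index(reference)
    registry = synthetic_hotspot_registry(reference)

    write_signature_tsv(signatures, out_dir / "signatures.tsv")
    from .hotspots import write_registry

    write_registry(registry, out_dir / "hotspots.json")

    n_total = sum(p.n_samples for p in profiles)
    child_seeds = np.random.SeedSequence(seed).generate_state(max(n_total, 1)) % (2**31)
    meta_rows, truth_rows = [], []
    vcf_dir = out_dir / "vcf"
    idx = 0
    seen_ids: set[str] = set()
    for profile in profiles:
        for i in range(profile.n_samples):
            sample_id = f"{profile.label}_{i + 1:02d}"
            if sample_id in seen_ids:
                raise ConfigurationError(f"duplicate sample id {sample_id}")
            seen_ids.add(sample_id)
            vcf_a, vcf_b, truth = simulate_sample(
                profile, reference, signatures, int(child_seeds[idx]),
                sample_id, vcf_dir, context_index, registry,
            )
            idx += 1
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "group": profile.label,
                    "tissue": profile.tissue,
                    "mmr_status": profile.mmr_status,
                    "vcf_a": str(vcf_a.relative_to(out_dir)),
                    "vcf_b": str(vcf_b.relative_to(out_dir)),
                }
            )
            row = {
                "sample_id": sample_id,
                "true_snv_count": truth.true_snv_count,
                "true_indel_count": truth.true_indel_count,
            }
            row.update({f"true_{k}": v for k, v in truth.true_exposures.items()})
            row.update({f"flag_{k}": v for k, v in truth.true_hotspot_flags.items()})
            truth_rows.append(row)
    pd.DataFrame(
        meta_rows,
        columns=["sample_id", "group", "tissue", "mmr_status", "vcf_a", "vcf_b"],
    ).to_csv(out_dir / "metadata.tsv", sep="\t", index=False)
    pd.DataFrame(truth_rows).to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    config_echo = {
        "seed": seed,
        "contig_length": contig_length,
        "profiles": [
            {
                "label": p.label,
                "n_samples": p.n_samples,
                "exposure_mean": dict(p.exposure_mean),
                "exposure_concentration": p.exposure_concentration,
                "snv_count": list(p.snv_count),
                "indel_count": list(p.indel_count),
                "hotspot_rates": dict(p.hotspot_rates),
                "depth_mean": p.depth_mean,
                "vaf_beta": list(p.vaf_beta),
                "contamination": p.contamination,
                "discordance": p.discordance,
                "tissue": p.tissue,
                "mmr_status": p.mmr_status,
            }
            for p in profiles
        ],
    }
    with open(out_dir / "config.json", "w") as fh:
        json.dump(config_echo, fh, indent=2, sort_keys=True)
    return out_dir
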