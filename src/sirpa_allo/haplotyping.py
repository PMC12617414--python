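"""Panel-based SIRPα IgV-domain haplotype calling.

The IgV domain (exon 3) of human SIRPA carries 16 polymorphic sites (15 SNPs
and one deletion) whose phased combinations define the named haplotypes V1,
V2, V9, NV1 and NV2.  Direct Sanger sequencing of the amplicon yields
*unphased* per-site genotypes, so a heterozygous individual may be consistent
with more than one haplotype pair ("Sanger ambiguity"); phased observations
(amplicon NGS) resolve each chromosome to a single panel haplotype or reveal
a novel one.

This module provides the panel model, the consistency-set caller for unphased
genotypes, the exact-match caller for phased haplotypes, the functional
collapse of rare V1-like alleles onto V1, and cohort-level genotype summaries.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("sirpa_allo")

MISSING = "."  #: per-site missing-call marker in unphased tables


class PanelError(ValueError):
    """Malformed or inconsistent panel input."""


class GenotypeInputError(ValueError):
    """Genotype data incompatible with the panel."""


class SiteType(str, Enum):
    SNP = "SNP"
    DELETION = "DELETION"


class CallStatus(str, Enum):
    UNIQUE = "UNIQUE"
    AMBIGUOUS = "AMBIGUOUS"
    NOVEL = "NOVEL"
    FAILED = "FAILED"


class CallMethod(str, Enum):
    SANGER_LIKE = "SANGER_LIKE"
    PHASED = "PHASED"


class FunctionalAllele(str, Enum):
    """Functional dichotomy used downstream: V2 vs everything V1-like."""

    V1LIKE = "V1LIKE"
    V2 = "V2"


@dataclass(frozen=True)
class VariantSite:
    """One polymorphic site, 1-based GRCh37/hg19 forward-strand coordinates."""

    site_id: str
    chrom: str
    position: int
    ref: str
    alt: str
    site_type: SiteType

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.ref, self.alt)


@dataclass(frozen=True)
class Haplotype:
    """A named phased allele vector over the panel's sites."""

    name: str
    alleles: tuple[str, ...]

    def hamming(self, other: "Haplotype | Sequence[str]") -> int:
        other_alleles = other.alleles if isinstance(other, Haplotype) else tuple(other)
        if len(other_alleles) != len(self.alleles):
            raise GenotypeInputError(
                f"cannot compare vectors of length {len(self.alleles)} and {len(other_alleles)}"
            )
        return sum(a != b for a, b in zip(self.alleles, other_alleles))


@dataclass(frozen=True)
class HaplotypePanel:
    sites: tuple[VariantSite, ...]
    haplotypes: tuple[Haplotype, ...]

    def __post_init__(self) -> None:
        if not self.haplotypes:
            raise PanelError("panel has no haplotypes")
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise PanelError("duplicate site_id in variant table")
        pos = [(s.chrom, s.position) for s in self.sites]
        for prev, cur in zip(pos, pos[1:]):
            if prev[0] == cur[0] and prev[1] >= cur[1]:
                raise PanelError("positions must be strictly increasing in table order")
        names = [h.name for h in self.haplotypes]
        if len(set(names)) != len(names):
            raise PanelError("duplicate haplotype names")
        vectors = [h.alleles for h in self.haplotypes]
        if len(set(vectors)) != len(vectors):
            raise PanelError("two panel haplotypes share an identical allele vector")
        for h in self.haplotypes:
            if len(h.alleles) != len(self.sites):
                raise PanelError(
                    f"haplotype {h.name} has {len(h.alleles)} alleles for {len(self.sites)} sites"
                )
            for a, s in zip(h.alleles, self.sites):
                if a not in s.alleles:
                    raise PanelError(
                        f"haplotype {h.name} carries {a!r} at {s.site_id}, "
                        f"expected {s.ref!r} or {s.alt!r}"
                    )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(h.name for h in self.haplotypes)

    def __getitem__(self, name: str) -> Haplotype:
        for h in self.haplotypes:
            if h.name == name:
                return h
        raise KeyError(name)


@dataclass(frozen=True)
class UnphasedGenotype:
    """Per-site unordered allele pairs for one subject; ``None`` = missing."""

    subject_id: str
    calls: tuple[tuple[str, str] | None, ...]

    @staticmethod
    def from_pair(subject_id: str, h1: Haplotype, h2: Haplotype) -> "UnphasedGenotype":
        """Synthesize the unphased genotype a pair of haplotypes would produce."""
        calls = tuple(tuple(sorted((a, b))) for a, b in zip(h1.alleles, h2.alleles))
        return UnphasedGenotype(subject_id, calls)


@dataclass(frozen=True)
class GenotypeCall:
    """Result of haplotype-pair inference for one subject.

    ``pairs`` holds every unordered haplotype-name pair consistent with the
    data; for phased calls novel vectors are retained in ``novel_haplotypes``.
    """

    subject_id: str
    status: CallStatus
    pairs: frozenset[frozenset[str]]
    method: CallMethod
    novel_haplotypes: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def unique_pair(self) -> tuple[str, str]:
        if len(self.pairs) != 1:
            raise ValueError(f"call for {self.subject_id} is not unique")
        (pair,) = self.pairs
        members = sorted(pair)
        return (members[0], members[-1])  # homozygote frozensets have one member


# ---------------------------------------------------------------------------
# Panel IO
# ---------------------------------------------------------------------------

_VARIANT_COLUMNS = ["site_id", "chrom", "position", "ref", "alt", "site_type"]


def _read_tsv(path: Path | str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message varies
        raise PanelError(f"{path}: {exc}") from exc


def load_variant_table(path: Path | str) -> tuple[VariantSite, ...]:
    df = _read_tsv(path)
    missing = set(_VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise PanelError(f"{path}: missing columns {sorted(missing)}")
    sites = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1 of the non-comment stream
        if row[_VARIANT_COLUMNS].isna().any():
            raise PanelError(f"{path}: malformed row at data line {line}")
        try:
            position = int(row["position"])
            site_type = SiteType(row["site_type"])
        except (ValueError, KeyError) as exc:
            raise PanelError(f"{path}: malformed row at data line {line}: {exc}") from exc
        sites.append(
            VariantSite(row["site_id"], row["chrom"], position, row["ref"], row["alt"], site_type)
        )
    return tuple(sites)


def load_panel(variant_table_path: Path | str, haplotype_table_path: Path | str) -> HaplotypePanel:
    """Load and validate a haplotype panel from its two TSV files."""
    sites = load_variant_table(variant_table_path)
    df = _read_tsv(haplotype_table_path)
    if "name" not in df.columns:
        raise PanelError(f"{haplotype_table_path}: missing 'name' column")
    site_ids = [s.site_id for s in sites]
    missing = set(site_ids) - set(df.columns)
    if missing:
        raise PanelError(f"{haplotype_table_path}: missing site columns {sorted(missing)}")
    haplotypes = []
    for i, row in df.iterrows():
        if row[["name", *site_ids]].isna().any():
            raise PanelError(f"{haplotype_table_path}: malformed row at data line {i + 2}")
        haplotypes.append(Haplotype(row["name"], tuple(row[sid] for sid in site_ids)))
    return HaplotypePanel(sites, tuple(haplotypes))


def default_panel() -> HaplotypePanel:
    """The packaged stand-in panel (synthetic allele vectors, published rsIDs)."""
    data = resources.files("sirpa_allo") / "data"
    with resources.as_file(data / "variant_sites.tsv") as vp, resources.as_file(
        data / "haplotypes.tsv"
    ) as hp:
        return load_panel(vp, hp)


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

def enumerate_consistent_pairs(g: UnphasedGenotype, panel: HaplotypePanel) -> GenotypeCall:
    """All unordered panel-haplotype pairs consistent with an unphased genotype.

    A pair (h_i, h_j), i = j allowed, is consistent when its site-wise allele
    multiset equals the observed unordered pair at every non-missing site.
    Missing sites act as wildcards, so they can only enlarge the pair set —
    mirroring how partial Sanger data inflates ambiguity.
    """
    if len(g.calls) != panel.n_sites:
        raise GenotypeInputError(
            f"genotype for {g.subject_id} has {len(g.calls)} calls for {panel.n_sites} sites"
        )
    pairs = set()
    for h1, h2 in itertools.combinations_with_replacement(panel.haplotypes, 2):
        ok = True
        for call, a, b in zip(g.calls, h1.alleles, h2.alleles):
            if call is not None and tuple(sorted((a, b))) != call:
                ok = False
                break
        if ok:
            pairs.add(frozenset((h1.name, h2.name)))
    if not pairs:
        status = CallStatus.FAILED
    elif len(pairs) == 1:
        status = CallStatus.UNIQUE
    else:
        status = CallStatus.AMBIGUOUS
    return GenotypeCall(g.subject_id, status, frozenset(pairs), CallMethod.SANGER_LIKE)


def call_phased(
    subject_id: str,
    observed_haplotypes: Sequence[Sequence[str]],
    panel: HaplotypePanel,
    max_mismatch: int = 0,
) -> GenotypeCall:
    """Assign two phased allele vectors to panel haplotypes, or label them novel.

    Each observed vector is matched to the unique panel haplotype within
    ``max_mismatch`` differences (default 0: exact-match-or-novel).  A vector
    with no admissible match — or a tied nearest match — is labelled
    ``NOVEL-<k>`` and its allele vector retained on the call.
    """
    if len(observed_haplotypes) != 2:
        raise GenotypeInputError("phased input must provide exactly two haplotype vectors")
    if max_mismatch < 0:
        raise GenotypeInputError("max_mismatch must be >= 0")
    names: list[str] = []
    novel: dict[str, tuple[str, ...]] = {}
    for vec in observed_haplotypes:
        vec = tuple(vec)
        if len(vec) != panel.n_sites:
            raise GenotypeInputError(
                f"phased vector for {subject_id} has {len(vec)} alleles for {panel.n_sites} sites"
            )
        dists = [(h.hamming(vec), h.name) for h in panel.haplotypes]
        best = min(d for d, _ in dists)
        hits = [n for d, n in dists if d == best]
        if best <= max_mismatch and len(hits) == 1:
            names.append(hits[0])
        else:
            label = f"NOVEL-{len(novel) + 1}"
            novel[label] = vec
            names.append(label)
    status = CallStatus.NOVEL if novel else CallStatus.UNIQUE
    return GenotypeCall(
        subject_id, status, frozenset({frozenset(names)}), CallMethod.PHASED, novel
    )


@dataclass(frozen=True)
class CollapseResult:
    """Functional collapse of a haplotype with its distance metadata."""

    allele: FunctionalAllele
    distance_to_v1: int
    distance_to_v2: int

    @property
    def tie(self) -> bool:
        return self.distance_to_v1 == self.distance_to_v2


def collapse_functional(h: Haplotype, panel: HaplotypePanel) -> CollapseResult:
    """Collapse a haplotype onto the V1-like/V2 functional dichotomy.

    Rare alleles (V9, NV1, NV2 and novel variants) are treated as V1-like
    because their allele repertoires resemble V1's; operationally a haplotype
    is V2 iff it is strictly nearer the panel's V2 vector than its V1 vector,
    with ties resolved to V1-like and flagged via :attr:`CollapseResult.tie`.
    """
    d1 = panel["V1"].hamming(h)
    d2 = panel["V2"].hamming(h)
    allele = FunctionalAllele.V2 if d2 < d1 else FunctionalAllele.V1LIKE
    result = CollapseResult(allele, d1, d2)
    if result.tie:
        logger.warning(
            "haplotype %s equidistant from V1 and V2 (d=%d); collapsed to V1LIKE", h.name, d1
        )
    return result


# ---------------------------------------------------------------------------
# Summaries and tabular IO
# ---------------------------------------------------------------------------

SUMMARY_CATEGORIES = ("V1/V1", "V2/V2", "ambiguous-het", "other")


def _categorize(call: GenotypeCall) -> str:
    if call.status is CallStatus.AMBIGUOUS:
        return "ambiguous-het"
    if call.status is CallStatus.UNIQUE:
        a, b = call.unique_pair
        if (a, b) == ("V1", "V1"):
            return "V1/V1"
        if (a, b) == ("V2", "V2"):
            return "V2/V2"
    return "other"


def genotype_summary(calls: Sequence[GenotypeCall]) -> pd.DataFrame:
    """Counts and percentages by genotype category, one decimal place.

    Mirrors cohort-level genotyping reports, e.g. 12 V1/V1 homozygotes among
    94 subjects being reported as 12.8%.
    """
    if not calls:
        raise GenotypeInputError("empty call list")
    counts = {c: 0 for c in SUMMARY_CATEGORIES}
    for call in calls:
        counts[_categorize(call)] += 1
    total = len(calls)
    return pd.DataFrame(
        {
            "category": list(counts),
            "count": list(counts.values()),
            "percent": [round(100.0 * n / total, 1) for n in counts.values()],
        }
    )


def read_unphased_table(path: Path | str, panel: HaplotypePanel) -> list[UnphasedGenotype]:
    """Read a subject × site table of unordered 'A/G'-style calls ('.' missing)."""
    df = _read_tsv(path)
    site_ids = [s.site_id for s in panel.sites]
    missing = set(site_ids) - set(df.columns)
    if missing:
        raise GenotypeInputError(f"{path}: missing site columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        calls: list[tuple[str, str] | None] = []
        for sid in site_ids:
            cell = row[sid]
            if pd.isna(cell) or cell == MISSING:
                calls.append(None)
            else:
                alleles = cell.split("/")
                if len(alleles) != 2:
                    raise GenotypeInputError(
                        f"{path}: bad call {cell!r} for {row['subject_id']} at {sid}"
                    )
                calls.append(tuple(sorted(alleles)))
        out.append(UnphasedGenotype(str(row["subject_id"]), tuple(calls)))
    return out


def read_phased_table(path: Path | str, panel: HaplotypePanel) -> dict[str, list[tuple[str, ...]]]:
    """Read subject_id / hap_index / allele-column phased haplotype vectors."""
    df = _read_tsv(path)
    site_ids = [s.site_id for s in panel.sites]
    missing = {"subject_id", "hap_index", *site_ids} - set(df.columns)
    if missing:
        raise GenotypeInputError(f"{path}: missing columns {sorted(missing)}")
    vectors: dict[str, list[tuple[str, ...]]] = {}
    for _, row in df.sort_values(["subject_id", "hap_index"]).iterrows():
        vectors.setdefault(str(row["subject_id"]), []).append(
            tuple(row[sid] for sid in site_ids)
        )
    for sid, vecs in vectors.items():
        if len(vecs) != 2:
            raise GenotypeInputError(f"{path}: subject {sid} has {len(vecs)} phased vectors")
    return vectors


def calls_to_frame(calls: Iterable[GenotypeCall]) -> pd.DataFrame:
    """Flatten calls for TSV output; ambiguous pair-sets are ';'-joined."""
    rows = []
    for c in calls:
        pair_strs = sorted("/".join(sorted(p)) if len(p) == 2 else f"{min(p)}/{min(p)}" for p in c.pairs)
        rows.append(
            {
                "subject_id": c.subject_id,
                "status": c.status.value,
                "method": c.method.value,
                "pairs": ";".join(pair_strs),
                "n_pairs": len(c.pairs),
            }
        )
    return pd.DataFrame(rows, columns=["subject_id", "status", "method", "pairs", "n_pairs"])
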