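"""Per-KO abundance quantification from multi-omic read counts.

The quantification chain mirrors standard practice for coupled
metagenomic (MG) / metatranscriptomic (MT) data:

1. subsample libraries to a common depth so gene-copy and transcript
   counts are comparable between layers and samples;
2. distribute multi-mapping reads fractionally across target genes;
3. normalise per-gene counts by effective gene length (the number of
   positions a read start can occupy);
4. sum length-normalised gene abundances into KO (KEGG Orthology)
   abundances: KOGA for the MG layer, KOTA for the MT layer;
5. take the per-KO ratio KOTA/KOGA as relative gene expression, i.e.
   transcription normalised to underlying gene copy number.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from fractions import Fraction
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "Layer",
    "GeneCatalogue",
    "OmicCounts",
    "ReadAssignment",
    "KOProfile",
    "MTOnlyPolicy",
    "subsample_counts",
    "weight_multimapped",
    "normalize_by_length",
    "aggregate_ko",
    "relative_expression",
    "write_ko_profiles",
    "read_ko_profiles",
    "read_protein_abundance",
]

DEFAULT_KO_PATTERN = re.compile(r"^K\d+$")

MT_ONLY_FLAG = "MT-only"


class Layer(str, Enum):
    """Omic layer of a count table: metagenome or metatranscriptome."""

    MG = "MG"
    MT = "MT"


class MTOnlyPolicy(str, Enum):
    """How to handle KOs with transcript signal but zero gene-copy signal.

    ``flag``: relative expression left undefined and the KO flagged
    ``MT-only``; such KOs are excluded from percentile ranking downstream.
    ``pseudocount``: the smallest non-zero KOGA is substituted as the
    denominator, yielding a finite (large) expression value.
    """

    FLAG = "flag"
    PSEUDOCOUNT = "pseudocount"


@dataclass(frozen=True)
class GeneCatalogue:
    """Gene catalogue joining gene identifiers to length and function.

    Parameters
    ----------
    effective_length
        Map gene_id -> effective length in nucleotides (>= 1), the
        normalisation denominator for read counts.
    ko_ids
        Map gene_id -> set of KO identifiers (possibly empty).
    """

    effective_length: Mapping[str, int]
    ko_ids: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for gene, length in self.effective_length.items():
            if length < 1:
                raise ValueError(
                    f"effective_length of gene {gene!r} must be >= 1, got {length}"
                )
        missing = set(self.effective_length) ^ set(self.ko_ids)
        if missing:
            raise ValueError(
                f"catalogue length/KO maps disagree on genes: {sorted(missing)[:5]}"
            )

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(self.effective_length)

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, int, Iterable[str]]],
        ko_pattern: re.Pattern[str] = DEFAULT_KO_PATTERN,
    ) -> "GeneCatalogue":
        lengths: dict[str, int] = {}
        kos: dict[str, frozenset[str]] = {}
        for gene_id, length, ko_iter in records:
            if gene_id in lengths:
                raise ValueError(f"duplicate gene_id {gene_id!r} in catalogue")
            ko_set = frozenset(ko_iter)
            for ko in ko_set:
                if not ko_pattern.match(ko):
                    raise ValueError(
                        f"KO id {ko!r} for gene {gene_id!r} does not match "
                        f"pattern {ko_pattern.pattern!r}"
                    )
            lengths[gene_id] = int(length)
            kos[gene_id] = ko_set
        return cls(effective_length=lengths, ko_ids=kos)

    @classmethod
    def read_tsv(
        cls, path, ko_pattern: re.Pattern[str] = DEFAULT_KO_PATTERN
    ) -> "GeneCatalogue":
        """Read a catalogue TSV: gene_id, effective_length, ko_ids (';'-sep)."""
        df = pd.read_csv(
            path, sep="\t", dtype={"gene_id": str, "ko_ids": str}, keep_default_na=False
        )
        required = {"gene_id", "effective_length", "ko_ids"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"catalogue {path} missing columns {sorted(required - set(df.columns))}"
            )

        def split(s: str) -> list[str]:
            s = s.strip()
            return [] if s in ("", "NA") else s.split(";")

        return cls.from_records(
            zip(df["gene_id"], df["effective_length"], df["ko_ids"].map(split)),
            ko_pattern=ko_pattern,
        )

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "gene_id": list(self.effective_length),
                "effective_length": [self.effective_length[g] for g in self.effective_length],
                "ko_ids": [";".join(sorted(self.ko_ids[g])) for g in self.effective_length],
            }
        )
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")


@dataclass(frozen=True)
class OmicCounts:
    """Per-gene read counts for one omic layer and one sample.

    Counts may be fractional after multi-mapping weighting; they are
    integers before (a requirement for subsampling).
    """

    layer: Layer
    sample_id: str
    counts: Mapping[str, float]

    def __post_init__(self) -> None:
        for gene, c in self.counts.items():
            if not math.isfinite(c) or c < 0:
                raise ValueError(f"count for gene {gene!r} must be finite and >= 0, got {c}")

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))

    def is_integer(self) -> bool:
        return all(float(c).is_integer() for c in self.counts.values())

    @classmethod
    def read_tsv(cls, path, layer: Layer, sample_id: str) -> "OmicCounts":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
        if not {"gene_id", "count"}.issubset(df.columns):
            raise ValueError(f"counts table {path} must have columns gene_id, count")
        return cls(layer=layer, sample_id=sample_id, counts=dict(zip(df["gene_id"], df["count"].astype(float))))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"gene_id": list(self.counts), "count": list(self.counts.values())}
        ).to_csv(path, sep="\t", index=False, lineterminator="\n")


@dataclass(frozen=True)
class ReadAssignment:
    """One read and the set of genes it maps to (>= 1)."""

    read_id: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"read {self.read_id!r} has an empty gene set")


@dataclass(frozen=True)
class KOProfile:
    """Per-KO abundance profile across omic layers.

    ``rel_expr`` is KOTA/KOGA where defined; ``None`` with the
    ``MT-only`` flag when KOGA is zero under the flagging policy.
    ``protein_abundance`` is an externally computed normalised spectral
    index, ingested as-is.
    """

    ko_id: str
    koga: float = 0.0
    kota: float = 0.0
    protein_abundance: Optional[float] = None
    rel_expr: Optional[float] = None
    flags: tuple[str, ...] = ()


def subsample_counts(counts: OmicCounts, depth: int, seed: int) -> OmicCounts:
    """Draw ``depth`` reads without replacement from an integer count table.

    Subsampling to identical depths makes gene-copy and transcript counts
    comparable across layers and samples. The draw is multivariate
    hypergeometric over genes, reproducible for a given seed.
    """
    if not counts.is_integer():
        raise ValueError(
            "subsampling requires integer read counts; subsample before "
            "multi-mapping weighting, not after"
        )
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    genes = sorted(counts.counts)
    totals = np.array([int(counts.counts[g]) for g in genes], dtype=np.int64)
    available = int(totals.sum())
    if depth > available:
        raise ValueError(
            f"requested depth {depth} exceeds available reads {available}"
        )
    if depth == available:
        drawn = totals
    else:
        rng = np.random.default_rng(seed)
        drawn = rng.multivariate_hypergeometric(totals, depth, method="marginals")
    return OmicCounts(
        layer=counts.layer,
        sample_id=counts.sample_id,
        counts={g: float(n) for g, n in zip(genes, drawn)},
    )


def weight_multimapped(
    assignments: Iterable[ReadAssignment],
    layer: Layer = Layer.MG,
    sample_id: str = "sample",
) -> OmicCounts:
    """Convert read-to-gene assignments into fractional per-gene counts.

    Each read contributes 1/k to each of the k genes it maps to, so the
    total count over genes equals the number of reads exactly (rational
    arithmetic internally).
    """
    acc: dict[str, Fraction] = {}
    n_reads = 0
    for a in assignments:
        if not a.gene_ids:
            raise ValueError(f"read {a.read_id!r} has an empty gene set")
        n_reads += 1
        w = Fraction(1, len(a.gene_ids))
        for g in a.gene_ids:
            acc[g] = acc.get(g, Fraction(0)) + w
    counts = {g: float(v) for g, v in acc.items()}
    return OmicCounts(layer=layer, sample_id=sample_id, counts=counts)


def normalize_by_length(
    counts: OmicCounts, catalogue: GeneCatalogue
) -> dict[str, float]:
    """Divide each gene's count by its effective length (reads/nt)."""
    out: dict[str, float] = {}
    for gene, c in counts.counts.items():
        if gene not in catalogue.effective_length:
            raise KeyError(f"gene {gene!r} has counts but is absent from the catalogue")
        out[gene] = c / catalogue.effective_length[gene]
    return out


def aggregate_ko(
    normalized: Mapping[str, float],
    catalogue: GeneCatalogue,
    multi_ko: str = "full",
) -> dict[str, float]:
    """Sum length-normalised gene abundances per KO.

    Genes without KO assignment are dropped. Genes with multiple KOs
    contribute their full abundance to each assigned KO by default
    (``multi_ko="full"``); ``"split"`` divides the abundance equally
    among the assigned KOs instead.
    """
    if multi_ko not in ("full", "split"):
        raise ValueError(f"unknown multi_ko policy {multi_ko!r}")
    out: dict[str, float] = {}
    for gene, value in normalized.items():
        kos = catalogue.ko_ids.get(gene, frozenset())
        if not kos:
            continue
        share = value if multi_ko == "full" else value / len(kos)
        for ko in kos:
            out[ko] = out.get(ko, 0.0) + share
    return out


def relative_expression(
    koga: Mapping[str, float],
    kota: Mapping[str, float],
    policy: MTOnlyPolicy = MTOnlyPolicy.FLAG,
    protein: Optional[Mapping[str, float]] = None,
) -> dict[str, KOProfile]:
    """Combine KOGA and KOTA maps into per-KO profiles with rel. expression.

    rel_expr = KOTA/KOGA where KOGA > 0; zero where KOTA is zero. KOs
    with KOTA > 0 but KOGA = 0 are handled per ``policy`` (see
    :class:`MTOnlyPolicy`). The union of the two key sets is processed.
    """
    for name, table in (("koga", koga), ("kota", kota)):
        for ko, v in table.items():
            if v < 0:
                raise ValueError(f"negative {name} value for {ko!r}: {v}")
    nonzero_ga = [v for v in koga.values() if v > 0]
    pseudo = min(nonzero_ga) if nonzero_ga else None
    protein = protein or {}

    profiles: dict[str, KOProfile] = {}
    for ko in sorted(set(koga) | set(kota)):
        ga = float(koga.get(ko, 0.0))
        ta = float(kota.get(ko, 0.0))
        flags: tuple[str, ...] = ()
        if ga > 0:
            rel: Optional[float] = ta / ga
        elif ta == 0:
            rel = 0.0
        elif policy is MTOnlyPolicy.PSEUDOCOUNT and pseudo is not None:
            rel = ta / pseudo
            flags = ("MT-only-pseudocount",)
        else:
            rel = None
            flags = (MT_ONLY_FLAG,)
        profiles[ko] = KOProfile(
            ko_id=ko,
            koga=ga,
            kota=ta,
            protein_abundance=protein.get(ko),
            rel_expr=rel,
            flags=flags,
        )
    return profiles


def read_protein_abundance(path) -> dict[str, float]:
    """Read a per-KO protein abundance TSV (ko_id, protein).

    Values are externally computed normalised spectral indices; they
    are ingested as-is and attached to profiles, never derived from
    spectra here.
    """
    df = pd.read_csv(path, sep="\t", dtype={"ko_id": str}, keep_default_na=False)
    if not {"ko_id", "protein"}.issubset(df.columns):
        raise ValueError(f"protein table {path} must have columns ko_id, protein")
    out: dict[str, float] = {}
    for ko, v in zip(df["ko_id"], df["protein"]):
        if v not in ("", "NA"):
            out[ko] = float(v)
    return out


def write_ko_profiles(profiles: Mapping[str, KOProfile], path) -> None:
    """Write profiles as TSV: ko_id, koga, kota, protein, rel_expr, flags."""
    rows = []
    for ko in sorted(profiles):
        p = profiles[ko]
        rows.append(
            {
                "ko_id": p.ko_id,
                "koga": repr(p.koga),
                "kota": repr(p.kota),
                "protein": "NA" if p.protein_abundance is None else repr(p.protein_abundance),
                "rel_expr": "NA" if p.rel_expr is None else repr(p.rel_expr),
                "flags": ";".join(p.flags) if p.flags else "NA",
            }
        )
    pd.DataFrame(rows, columns=["ko_id", "koga", "kota", "protein", "rel_expr", "flags"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_ko_profiles(path) -> dict[str, KOProfile]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, KOProfile] = {}
    for _, row in df.iterrows():
        out[row["ko_id"]] = KOProfile(
            ko_id=row["ko_id"],
            koga=float(row["koga"]),
            kota=float(row["kota"]),
            protein_abundance=None if row["protein"] == "NA" else float(row["protein"]),
            rel_expr=None if row["rel_expr"] == "NA" else float(row["rel_expr"]),
            flags=tuple(row["flags"].split(";")) if row["flags"] != "NA" else (),
        )
    return out
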