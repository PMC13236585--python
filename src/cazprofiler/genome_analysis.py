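"""Repertoire analytics over an annotated genome collection.

Covers taxon-level presence calls (a family is present in a taxon when at
least 20% of its genomes carry >= 1 copy), substrate-enrichment z-scores
over genus-wise mean copy numbers, pairwise Jaccard similarity of
presence/absence repertoires, and a modified Jaccard index for intra-gene
(ORF-level) co-occurrence of family pairs.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cazprofiler.substrate_scheme import SubstrateScheme

logger = logging.getLogger(__name__)


@dataclass
class GenomeFeatureTable:
    """Copy-number matrix (genomes x families) plus per-genome taxonomy."""

    copies: pd.DataFrame  # index: genome, columns: family, integer copies
    taxonomy: pd.DataFrame  # index: genome, columns: phylum, genus, species

    def __post_init__(self) -> None:
        missing = set(self.copies.index) - set(self.taxonomy.index)
        if missing:
            raise ValueError(f"genomes without taxonomy: {sorted(missing)[:5]}")
        if (self.copies.values < 0).any():
            raise ValueError("copy numbers must be non-negative")

    @classmethod
    def from_long(cls, copy_df: pd.DataFrame, taxonomy_df: pd.DataFrame) -> "GenomeFeatureTable":
        mat = (
            copy_df.pivot_table(index="genome", columns="family", values="copies",
                                aggfunc="sum", fill_value=0)
            .astype(int)
        )
        tax = taxonomy_df.set_index("genome")
        mat = mat.reindex(tax.index, fill_value=0)
        return cls(copies=mat, taxonomy=tax)


@dataclass(frozen=True)
class EnrichmentScore:
    genus: str
    substrate: str
    mean_copy: float
    z: float  # NaN when the across-genus sd is 0


@dataclass(frozen=True)
class CooccurrencePair:
    genus: str
    family_a: str
    family_b: str
    n_both: int
    n_a: int
    n_b: int
    index: float
    reportable: bool = False


def taxon_presence(
    table: GenomeFeatureTable, rank: str, threshold: float = 0.20
) -> pd.DataFrame:
    """Boolean taxon x family presence matrix.

    A family is present in a taxon iff the fraction of the taxon's genomes
    carrying at least one copy is >= ``threshold`` (inclusive).
    """
    if rank not in table.taxonomy.columns:
        raise ValueError(f"unknown taxonomic rank {rank!r}")
    carrier = (table.copies >= 1).astype(float)
    frac = carrier.groupby(table.taxonomy[rank]).mean()
    return frac >= threshold


def substrate_enrichment_z(
    table: GenomeFeatureTable,
    scheme: SubstrateScheme,
    substrates: list[str],
    level: int,
    rank: str = "genus",
) -> list[EnrichmentScore]:
    """z-scores of the genus-wise mean total copy number per substrate.

    Per genus: mean over its genomes of the summed copies of families
    labelled with the substrate; z standardised across genera with the
    sample (n-1) standard deviation.  A zero sd yields missing (NaN) z.
    """
    genera = table.taxonomy[rank]
    if genera.nunique() < 2:
        raise ValueError("need at least two genera to standardise z-scores")
    out: list[EnrichmentScore] = []
    for substrate in substrates:
        fams = [
            f for f in table.copies.columns
            if substrate in scheme.substrates_at(f, level)
        ]
        per_genome = table.copies[fams].sum(axis=1) if fams else pd.Series(0, index=table.copies.index)
        means = per_genome.groupby(genera).mean()
        sd = means.std(ddof=1)
        if sd == 0 or math.isnan(sd):
            logger.warning("substrate %s: zero variance across genera; z missing", substrate)
            zs = pd.Series(np.nan, index=means.index)
        else:
            zs = (means - means.mean()) / sd
        out.extend(
            EnrichmentScore(genus=g, substrate=substrate,
                            mean_copy=float(means[g]), z=float(zs[g]))
            for g in means.index
        )
    return out


def repertoire_jaccard(
    table: GenomeFeatureTable,
    rank: str = "species",
    min_genomes: int = 4,
    presence_threshold: float = 0.20,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Pairwise Jaccard similarity/distance of taxon family repertoires.

    Only taxa represented by at least ``min_genomes`` genomes enter.  Two
    empty repertoires compare as identical (J = 1, logged).
    """
    counts = table.taxonomy[rank].value_counts()
    keep = sorted(counts[counts >= min_genomes].index)
    presence = taxon_presence(table, rank, presence_threshold).loc[keep]
    sets = {t: frozenset(presence.columns[presence.loc[t]]) for t in keep}
    n = len(keep)
    sim = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        a, b = sets[keep[i]], sets[keep[j]]
        if not a and not b:
            logger.info("taxa %s and %s both have empty repertoires; J := 1", keep[i], keep[j])
            jac = 1.0
        else:
            jac = len(a & b) / len(a | b)
        sim[i, j] = sim[j, i] = jac
    return keep, sim, 1.0 - sim


def cooccurrence_index(
    orf_df: pd.DataFrame,
    taxonomy: pd.DataFrame,
    min_genomes: int = 10,
    report_threshold: float = 0.2,
    cardinality_universe: str = "restricted",
) -> list[CooccurrencePair]:
    """Modified Jaccard index of family pairs sharing ORFs, per genus.

    ORFs with at least two distinct families are selected first; for each
    family pair the numerator is the number of such ORFs containing both,
    normalised by the smaller of the two families' ORF counts.  With
    ``cardinality_universe="restricted"`` (default) the per-family counts
    are taken over the same multi-family ORF set; ``"all"`` counts over
    every ORF.  Only genera with >= ``min_genomes`` genomes are evaluated.

    ``orf_df`` columns: genome, orf_id, families (iterable of family ids).
    ``taxonomy`` columns include genome, genus.
    """
    if cardinality_universe not in ("restricted", "all"):
        raise ValueError("cardinality_universe must be 'restricted' or 'all'")
    tax = taxonomy.set_index("genome") if "genome" in taxonomy.columns else taxonomy
    genome_counts = tax["genus"].value_counts()
    qualifying = set(genome_counts[genome_counts >= min_genomes].index)

    pairs: list[CooccurrencePair] = []
    genus_of = tax["genus"]
    df = orf_df.assign(genus=orf_df["genome"].map(genus_of))
    for genus, sub in df.groupby("genus", sort=True):
        if genus not in qualifying:
            continue
        orf_sets = [frozenset(f) for f in sub["families"]]
        multi = [s for s in orf_sets if len(s) >= 2]
        universe = multi if cardinality_universe == "restricted" else orf_sets
        card: dict[str, int] = {}
        for s in universe:
            for fam in s:
                card[fam] = card.get(fam, 0) + 1
        both: dict[tuple[str, str], int] = {}
        for s in multi:
            for a, b in itertools.combinations(sorted(s), 2):
                both[(a, b)] = both.get((a, b), 0) + 1
        for (a, b), n_both in sorted(both.items()):
            n_a, n_b = card.get(a, 0), card.get(b, 0)
            denom = min(n_a, n_b)
            if denom == 0:
                continue
            pairs.append(
                CooccurrencePair(
                    genus=genus, family_a=a, family_b=b,
                    n_both=n_both, n_a=n_a, n_b=n_b,
                    index=n_both / denom,
                    reportable=n_both / denom >= report_threshold,
                )
            )
    return pairs
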