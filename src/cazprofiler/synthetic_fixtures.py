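"""Seeded synthetic fixtures for every input the pipeline consumes.

``make_families`` plants per-family motifs (with clade structure so blocked
cross-validation is exercised, one parent family with two sub-motif
subfamilies, and a decoy negative pool).  ``make_catalogue_and_reads``
backtranslates modules into a nucleotide gene catalogue, samples reads
with substitution errors, writes a name-grouped SAM, and computes the
expected per-family counts by its own interval bookkeeping — independent
of the profiling module, so the expectation is a true oracle.
``make_genome_collection`` emits copy-number/taxonomy/ORF tables with a
planted always-co-occurring family pair and an undersized genus.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

from cazprofiler.calibration import FamilyDefinition
from cazprofiler.io_formats import (
    DomainAnnotation,
    SequenceRecord,
    write_domain_table,
    write_fasta,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"

# fixed arbitrary backtranslation table: protein-space truth maps exactly
# onto nucleotide-space domains via the x3 coordinate rule
CODON_OF = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

_CLASS_CYCLE = ("GH", "GT", "PL", "CE", "CBM")


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for the synthetic data.

    Defaults describe a small but structured benchmark: six families of
    ~30 members drawn from six 60%-identity clades each (so blocking has
    real groups), 90-residue modules, 40 catalogue genes, paired-end
    100 bp reads.
    """

    seed: int = 0
    n_families: int = 6
    motif_len: int = 90
    per_family_n: int = 30
    substitution_rate: float = 0.05
    n_genes: int = 40
    reads_per_sample: int = 5000
    read_len: int = 100
    error_rate: float = 0.0
    paired: bool = True
    n_clades: int = 6
    clade_divergence: float = 0.45
    n_holdout_per_family: int = 6

    def __post_init__(self) -> None:
        for name in ("n_families", "motif_len", "per_family_n", "n_genes",
                     "reads_per_sample", "read_len", "n_clades"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("substitution_rate", "error_rate", "clade_divergence"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.motif_len < 10:
            raise ValueError("motif_len < 10 yields degenerate models")


@dataclass
class FamilyFixture:
    families: dict[str, FamilyDefinition]
    hierarchy: pd.DataFrame  # family_id, parent, cazy_class
    negative_pool: list[SequenceRecord]
    holdout_targets: list[SequenceRecord]  # held-out proteins, planted + decoys
    holdout_truth: list[DomainAnnotation]  # protein-space truth intervals
    family_of_sequence: dict[str, str] = field(default_factory=dict)


@dataclass
class CatalogueFixture:
    genes: list[SequenceRecord]
    domains: list[DomainAnnotation]  # nucleotide space
    sam_path: Path
    expected_counts: dict[str, float]
    expected_total: float


@dataclass
class GenomeCollectionFixture:
    copy_table: pd.DataFrame  # genome, family, copies (long form)
    taxonomy: pd.DataFrame  # genome, phylum, genus, species
    orf_table: pd.DataFrame  # genome, orf_id, families (tuple)
    planted_pair: tuple[str, str]
    planted_genus: str
    undersized_genus: str


# ---------------------------------------------------------------------------
# Sequence-level helpers
# ---------------------------------------------------------------------------

def _random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


def _mutate_protein(rng: random.Random, seq: str, rate: float) -> str:
    out = []
    for aa in seq:
        if rng.random() < rate:
            out.append(rng.choice([x for x in AMINO_ACIDS if x != aa]))
        else:
            out.append(aa)
    return "".join(out)


def backtranslate(protein: str) -> str:
    return "".join(CODON_OF[aa] for aa in protein)


def _family_ids(n: int) -> list[str]:
    return [f"{_CLASS_CYCLE[i % len(_CLASS_CYCLE)]}{i + 1}" for i in range(n)]


# ---------------------------------------------------------------------------
# Families
# ---------------------------------------------------------------------------

def _make_member(
    rng: random.Random,
    fid: str,
    idx: int,
    clade_ancestor: str,
    rate: float,
) -> tuple[SequenceRecord, SequenceRecord, DomainAnnotation]:
    """One full-length protein with its module and protein-space truth."""
    module_seq = _mutate_protein(rng, clade_ancestor, rate)
    left = _random_protein(rng, rng.randint(20, 60))
    right = _random_protein(rng, rng.randint(20, 60))
    start = len(left) + 1
    end = len(left) + len(module_seq)
    sid = f"{fid}|p{idx:03d}"
    full = SequenceRecord(id=sid, seq=left + module_seq + right)
    module = SequenceRecord(
        id=f"{sid}/{start}-{end}",
        seq=module_seq,
        description=f"source={sid} interval={start}-{end}",
    )
    truth = DomainAnnotation(sid, fid, start, end, "protein")
    return full, module, truth


def make_families(spec: FixtureSpec, outdir: str | Path | None = None) -> FamilyFixture:
    """Generate the family sequence sets, hierarchy, decoys and holdouts."""
    rng = random.Random(spec.seed * 1_000_003 + 1)
    ids = _family_ids(spec.n_families)
    families: dict[str, FamilyDefinition] = {}
    family_of_sequence: dict[str, str] = {}
    holdout_targets: list[SequenceRecord] = []
    holdout_truth: list[DomainAnnotation] = []
    hierarchy_rows: list[dict] = []

    # the first family becomes a parent with two sub-motif subfamilies
    parent_id = ids[0]
    sub_ids = [f"{parent_id}_1", f"{parent_id}_2"]

    def build_family(fid: str, ancestor: str, parent: str | None) -> None:
        clade_ancestors = [
            _mutate_protein(rng, ancestor, spec.clade_divergence)
            for _ in range(spec.n_clades)
        ]
        modules: list[SequenceRecord] = []
        fulls: dict[str, SequenceRecord] = {}
        for i in range(spec.per_family_n):
            clade = clade_ancestors[i % spec.n_clades]
            full, module, _ = _make_member(rng, fid, i, clade, spec.substitution_rate)
            modules.append(module)
            fulls[full.id] = full
            family_of_sequence[full.id] = fid
        for i in range(spec.n_holdout_per_family):
            clade = clade_ancestors[rng.randrange(spec.n_clades)]
            full, _, truth = _make_member(
                rng, fid, 900 + i, clade, spec.substitution_rate
            )
            holdout_targets.append(full)
            holdout_truth.append(truth)
            if parent is not None:
                # a subfamily module is also a module of its parent family
                holdout_truth.append(
                    DomainAnnotation(truth.gene_id, parent, truth.start,
                                     truth.end, "protein")
                )
        families[fid] = FamilyDefinition(
            family_id=fid,
            parent=parent,
            member_modules=modules,
            full_sequences=fulls,
            alignment=modules,  # substitution-only members: ungapped MSA
        )
        hierarchy_rows.append(
            {"family_id": fid, "parent": parent or ".",
             "cazy_class": families[fid].cazy_class}
        )

    for fid in ids:
        ancestor = _random_protein(rng, spec.motif_len)
        build_family(fid, ancestor, None)
        if fid == parent_id:
            for sub in sub_ids:
                sub_ancestor = _mutate_protein(rng, ancestor, 0.30)
                build_family(sub, sub_ancestor, parent_id)

    negative_pool = [
        SequenceRecord(id=f"decoy{i:03d}", seq=_random_protein(rng, rng.randint(120, 260)))
        for i in range(40)
    ]
    # motif-free holdout decoys: negative controls for annotation
    for i in range(10):
        holdout_targets.append(
            SequenceRecord(id=f"neg{i:03d}", seq=_random_protein(rng, rng.randint(120, 260)))
        )

    hierarchy = pd.DataFrame(hierarchy_rows)
    fixture = FamilyFixture(
        families=families,
        hierarchy=hierarchy,
        negative_pool=negative_pool,
        holdout_targets=holdout_targets,
        holdout_truth=holdout_truth,
        family_of_sequence=family_of_sequence,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for fid, fam in families.items():
            write_fasta(list(fam.full_sequences.values()), outdir / f"{fid}.faa")
            write_fasta(fam.member_modules, outdir / f"{fid}.modules.faa")
            write_fasta(fam.alignment, outdir / f"{fid}.modules.aln.faa")
        write_fasta(negative_pool, outdir / "negative_pool.faa")
        write_fasta(holdout_targets, outdir / "holdout_targets.faa")
        hierarchy.to_csv(outdir / "hierarchy.tsv", sep="\t", index=False)
        write_domain_table(holdout_truth, outdir / "truth_holdout_domains.tsv")
    return fixture


# ---------------------------------------------------------------------------
# Catalogue + reads
# ---------------------------------------------------------------------------

def _random_nt(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(NUCLEOTIDES) for _ in range(length))


def make_catalogue_and_reads(
    spec: FixtureSpec,
    families: FamilyFixture,
    outdir: str | Path,
    sample_id: str = "sample1",
    depth_factor: int = 1,
) -> CatalogueFixture:
    """Build a nucleotide gene catalogue, sample reads, and write a SAM.

    Genes are backtranslated family modules embedded in random filler; a
    quarter of genes carry no domain (negative controls) and some carry
    two.  Reads are drawn approximately uniformly per gene position with
    substitution errors only, so NM and identity are analytic.  The
    expected per-family fractional counts are accumulated here with
    independent bookkeeping (interval overlap + w/k splitting), not by
    calling the profiler.
    """
    rng = random.Random(spec.seed * 1_000_003 + 2)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    module_pool: list[tuple[str, str]] = []  # (family_id, module protein seq)
    for fid, fam in families.families.items():
        for m in fam.member_modules:
            module_pool.append((fid, m.seq))

    genes: list[SequenceRecord] = []
    domains: list[DomainAnnotation] = []
    min_gene_len = 150
    for g in range(spec.n_genes):
        gid = f"g{g:03d}"
        n_domains = 0 if g % 4 == 3 else (2 if g % 5 == 0 else 1)
        parts: list[str] = [_random_nt(rng, rng.randint(60, 200))]
        pos = len(parts[0])
        for _ in range(n_domains):
            fid, mod = module_pool[rng.randrange(len(module_pool))]
            nt = backtranslate(mod)
            domains.append(
                DomainAnnotation(gid, fid, pos + 1, pos + len(nt), "nucleotide")
            )
            parts.append(nt)
            pos += len(nt)
            filler = _random_nt(rng, rng.randint(60, 200))
            parts.append(filler)
            pos += len(filler)
        seq = "".join(parts)
        if len(seq) < min_gene_len:
            seq += _random_nt(rng, min_gene_len - len(seq))
        genes.append(SequenceRecord(id=gid, seq=seq))

    if spec.read_len > min(len(g.seq) for g in genes):
        raise ValueError("read_len exceeds the shortest catalogue gene")

    # --- sample reads and keep the expected-profile books ------------------
    domains_by_gene: dict[str, list[DomainAnnotation]] = {}
    for i, d in enumerate(domains):
        domains_by_gene.setdefault(d.gene_id, []).append(d)
    instance_id = {id(d): i for i, d in enumerate(domains)}

    gene_weights = [len(g.seq) - spec.read_len + 1 for g in genes]
    total_positions = sum(gene_weights)

    expected_counts: dict[str, float] = {}
    expected_total = 0.0
    sam_path = outdir / f"{sample_id}.sam"
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": g.id, "LN": len(g.seq)} for g in genes],
        }
    )
    ref_id = {g.id: i for i, g in enumerate(genes)}

    def sample_mate(gene: SequenceRecord) -> tuple[int, str, int]:
        start0 = rng.randrange(len(gene.seq) - spec.read_len + 1)
        bases = list(gene.seq[start0 : start0 + spec.read_len])
        nm = 0
        for j in range(len(bases)):
            if rng.random() < spec.error_rate:
                bases[j] = rng.choice([x for x in NUCLEOTIDES if x != bases[j]])
                nm += 1
        return start0, "".join(bases), nm

    def book_mate(gene: SequenceRecord, start0: int, nm: int, weight: float) -> None:
        nonlocal expected_total
        identity = 100.0 * (1.0 - nm / spec.read_len)
        if not (spec.read_len > 45 and identity > 97.0):
            return
        expected_total += weight
        s1, e1 = start0 + 1, start0 + spec.read_len
        hit = {
            instance_id[id(d)]
            for d in domains_by_gene.get(gene.id, [])
            if d.start <= e1 and s1 <= d.end
        }
        if hit:
            share = weight / len(hit)
            for inst in hit:
                fam = domains[inst].family
                expected_counts[fam] = expected_counts.get(fam, 0.0) + share

    # depth_factor > 1 writes each sampled fragment that many times under
    # distinct names: exact depth scaling, so RPKM must be invariant
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as sam:
        for r in range(spec.reads_per_sample):
            pick = rng.randrange(total_positions)
            gi = 0
            while pick >= gene_weights[gi]:
                pick -= gene_weights[gi]
                gi += 1
            gene = genes[gi]
            n_mates = 2 if spec.paired else 1
            weight = 0.5 if spec.paired else 1.0
            mates = [sample_mate(gene) for _ in range(n_mates)]
            for dup in range(depth_factor):
                name = f"r{r:07d}" if depth_factor == 1 else f"r{r:07d}.{dup}"
                for mate, (start0, seq, nm) in enumerate(mates, start=1):
                    book_mate(gene, start0, nm, weight)
                    rec = pysam.AlignedSegment(header)
                    rec.query_name = name
                    rec.query_sequence = seq
                    rec.flag = (0x1 | (0x40 if mate == 1 else 0x80)) if spec.paired else 0
                    rec.reference_id = ref_id[gene.id]
                    rec.reference_start = start0
                    rec.mapping_quality = 60
                    rec.cigarstring = f"{spec.read_len}M"
                    rec.set_tag("NM", nm)
                    sam.write(rec)

    write_fasta(genes, outdir / "catalogue.fna")
    write_domain_table(domains, outdir / "catalogue_domains.tsv")
    pd.DataFrame(
        [{"family": f, "expected_count": c} for f, c in sorted(expected_counts.items())]
    ).to_csv(outdir / "truth_expected_counts.tsv", sep="\t", index=False)
    return CatalogueFixture(
        genes=genes,
        domains=domains,
        sam_path=sam_path,
        expected_counts=expected_counts,
        expected_total=expected_total,
    )


# ---------------------------------------------------------------------------
# Genome collection
# ---------------------------------------------------------------------------

def make_genome_collection(
    spec: FixtureSpec, outdir: str | Path | None = None
) -> GenomeCollectionFixture:
    """Copy-number, taxonomy and ORF-composition tables with planted truth.

    Genus A (12 genomes) carries a planted family pair that always shares
    ORFs (expected co-occurrence index 1.0); genus C has 8 genomes, below
    the 10-genome evaluation threshold.
    """
    rng = random.Random(spec.seed * 1_000_003 + 3)
    fam_ids = _family_ids(max(spec.n_families, 4))
    pair = (fam_ids[0], fam_ids[1])

    genus_sizes = {"GenusA": 12, "GenusB": 15, "GenusC": 8, "GenusD": 10}
    phylum_of = {"GenusA": "PhylumX", "GenusB": "PhylumX",
                 "GenusC": "PhylumY", "GenusD": "PhylumY"}

    tax_rows, copy_rows, orf_rows = [], [], []
    for genus, size in genus_sizes.items():
        for i in range(size):
            genome = f"{genus}.gen{i:02d}"
            species = f"{genus}_sp{i % 2 + 1}"
            tax_rows.append(
                {"genome": genome, "phylum": phylum_of[genus],
                 "genus": genus, "species": species}
            )
            for fam in fam_ids:
                lam = 2.0 if (genus == "GenusA" and fam in pair) else 0.8
                copies = _poisson(rng, lam)
                if copies:
                    copy_rows.append({"genome": genome, "family": fam, "copies": copies})
            # ORF compositions: multi-family ORFs plus single-family ones
            orf_n = 0
            if genus == "GenusA":
                # the planted pair co-occurs in every ORF where either appears
                for _ in range(2):
                    orf_rows.append(
                        {"genome": genome, "orf_id": f"{genome}.orf{orf_n:02d}",
                         "families": ",".join(pair)}
                    )
                    orf_n += 1
            for _ in range(3):
                pool = [f for f in fam_ids if f not in pair]
                k = rng.choice([1, 2, 2, 3])
                fams = sorted(rng.sample(pool, min(k, len(pool))))
                orf_rows.append(
                    {"genome": genome, "orf_id": f"{genome}.orf{orf_n:02d}",
                     "families": ",".join(fams)}
                )
                orf_n += 1

    taxonomy = pd.DataFrame(tax_rows)
    copy_table = pd.DataFrame(copy_rows)
    orf_table = pd.DataFrame(orf_rows)
    orf_table["families"] = orf_table["families"].apply(lambda s: tuple(s.split(",")))

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        copy_table.to_csv(outdir / "copy_numbers.tsv", sep="\t", index=False)
        taxonomy.to_csv(outdir / "taxonomy.tsv", sep="\t", index=False)
        out = orf_table.copy()
        out["families"] = out["families"].apply(",".join)
        out.to_csv(outdir / "orf_composition.tsv", sep="\t", index=False)
    return GenomeCollectionFixture(
        copy_table=copy_table,
        taxonomy=taxonomy,
        orf_table=orf_table,
        planted_pair=pair,
        planted_genus="GenusA",
        undersized_genus="GenusC",
    )


def _poisson(rng: random.Random, lam: float) -> int:
    # Knuth's method; lam is small here
    import math

    threshold = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= threshold:
            return k
        k += 1
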