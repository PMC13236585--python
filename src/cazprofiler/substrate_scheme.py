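"""Hierarchical glycan substrate scheme: loading, aggregation, ratios.

Families map to substrate labels at three nested levels (e.g. level 1
dietary fibre -> level 2 non-starch polysaccharide -> level 3 cellulose).
Families are polyspecific by design: a family's RPKM is added to *each* of
its substrates, so substrate sums are intentionally not a partition of
total RPKM.  Families missing from the scheme are reported under the
reserved key ``unannotated``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from cazprofiler.profiling import CazyProfile

UNANNOTATED = "unannotated"
LEVELS = (1, 2, 3)


def example_scheme_path() -> Path:
    """Path of the small scheme shipped with the package (includes the
    classic polyspecific CBM2 cellulose/hemicellulose/chitin example)."""
    return Path(__file__).parent / "data" / "example_scheme.tsv"


@dataclass
class SubstrateScheme:
    labels: dict[str, set[tuple[int, str]]] = field(default_factory=dict)
    origin: dict[str, set[str]] = field(default_factory=dict)
    function_at_origin: dict[str, set[str]] = field(default_factory=dict)
    parent_of: dict[tuple[int, str], str] = field(default_factory=dict)

    def substrates_at(self, family_id: str, level: int) -> set[str]:
        return {s for lv, s in self.labels.get(family_id, set()) if lv == level}


def load_scheme(path: str | Path) -> SubstrateScheme:
    """Load and validate a substrate scheme TSV.

    Columns: family_id, level1, level2, level3, origin, function_at_origin;
    multiple rows per family encode polyspecificity.  Every level-3
    substrate must have a single level-2 parent, and every level-2 a single
    level-1 parent, across all rows.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["family_id", "level1", "level2", "level3", "origin", "function_at_origin"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    scheme = SubstrateScheme()
    for row in df.itertuples():
        fam = row.family_id
        for child_key, parent in (
            ((3, row.level3), row.level2),
            ((2, row.level2), row.level1),
        ):
            known = scheme.parent_of.get(child_key)
            if known is not None and known != parent:
                raise ValueError(
                    f"substrate {child_key[1]!r} (level {child_key[0]}) has "
                    f"conflicting parents {known!r} and {parent!r}"
                )
            scheme.parent_of[child_key] = parent
        scheme.labels.setdefault(fam, set()).update(
            {(1, row.level1), (2, row.level2), (3, row.level3)}
        )
        if isinstance(row.origin, str) and row.origin != ".":
            scheme.origin.setdefault(fam, set()).add(row.origin)
        if isinstance(row.function_at_origin, str) and row.function_at_origin != ".":
            scheme.function_at_origin.setdefault(fam, set()).add(row.function_at_origin)
    return scheme


@dataclass
class SubstrateAbundance:
    sample_id: str
    level: int
    abundance: dict[str, float]


def aggregate(
    profile: CazyProfile | dict[str, float],
    scheme: SubstrateScheme,
    level: int,
    sample_id: str | None = None,
) -> SubstrateAbundance:
    """Sum family RPKMs per substrate label at one hierarchy level."""
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    if isinstance(profile, CazyProfile):
        rpkm = profile.rpkm
        sample_id = sample_id or profile.sample_id
    else:
        rpkm = profile
        sample_id = sample_id or "sample"
    abundance: dict[str, float] = {}
    for fam, value in rpkm.items():
        substrates = scheme.substrates_at(fam, level)
        if not substrates:
            abundance[UNANNOTATED] = abundance.get(UNANNOTATED, 0.0) + value
            continue
        for s in substrates:
            abundance[s] = abundance.get(s, 0.0) + value
    return SubstrateAbundance(sample_id=sample_id, level=level, abundance=abundance)


def substrate_ratio(
    profile: CazyProfile | dict[str, float],
    scheme: SubstrateScheme,
    numerator: str,
    denominator: str,
    level: int,
) -> float:
    """Ratio of two substrate abundances (e.g. mucin / dietary fibre).

    Expects pseudocounted RPKMs so the denominator cannot vanish.
    """
    agg = aggregate(profile, scheme, level)
    den = agg.abundance.get(denominator, 0.0)
    if den == 0.0:
        raise ValueError(
            f"denominator substrate {denominator!r} has zero abundance; "
            "apply the RPKM pseudocount first (apply_pseudocount)"
        )
    return agg.abundance.get(numerator, 0.0) / den


def write_abundance_table(abundance: SubstrateAbundance, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"sample_id": abundance.sample_id, "level": abundance.level,
             "substrate": s, "rpkm": f"{v:.6f}"}
            for s, v in sorted(abundance.abundance.items())
        ]
    ).to_csv(path, sep="\t", index=False)
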