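"""Keyword census of sugar transporters and glycolytic enzymes.

The screen works on free-text annotation products.  A feature counts as
a sugar transporter only if its product contains every gate term
("sugar" and "transporter" by default, case-insensitive substrings).
Gated features are then binned into the three uptake-system families:

* ABC — ATP-binding cassette importers,
* PTS — phosphoenolpyruvate phosphotransferase systems,
* MFS — major facilitator superfamily (secondary) transporters.

The three-letter abbreviations are matched case-sensitively on word
boundaries (so "abc" buried in an unrelated word never matches), while
spelled-out family names match case-insensitively.  A product matching
tokens of two families increments both counts; each feature contributes
at most one count per family.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotations import GenomeAnnotation

logger = logging.getLogger(__name__)

TRANSPORTER_CATEGORIES = ("ABC", "PTS", "MFS")

DEFAULT_SUBTYPE_TOKENS: dict[str, list[str]] = {
    "ABC": ["ABC", "ATP-binding cassette"],
    "PTS": ["PTS", "phosphotransferase"],
    "MFS": ["MFS", "major facilitator"],
}

# Glycolytic-enzyme search terms. The hexokinase entry carries the
# alternate terms used for organisms annotating the reaction under other
# names. Users with a curated enzyme list should override this mapping.
DEFAULT_ENZYME_TERMS: dict[str, list[str]] = {
    "HK": ["hexokinase", "sugar kinase", "glucokinase", "ROK family kinase"],
    "PFK": ["6-phosphofructokinase", "phosphofructokinase"],
    "PYK": ["pyruvate kinase"],
    "G6PD": ["glucose-6-phosphate dehydrogenase", "glucose 6-phosphate 1-dehydrogenase"],
    "6PGD": ["6-phosphogluconate dehydrogenase", "phosphogluconate dehydrogenase"],
    "RPI": ["ribose-5-phosphate isomerase", "ribose 5-phosphate isomerase"],
    "EDD": ["phosphogluconate dehydratase", "6-phosphogluconate dehydratase"],
    "KDGP": [
        "2-keto-3-deoxy-6-phosphogluconate aldolase",
        "KHG/KDPG aldolase",
        "2-dehydro-3-deoxyphosphogluconate aldolase",
        "KDPG aldolase",
    ],
    "PGM": ["phosphoglucomutase"],
}

# Three essential enzymes per pathway; G6PD is deliberately shared
# between the oxidative PPP and ED upper branch.
DEFAULT_PATHWAYS: dict[str, frozenset[str]] = {
    "EMP": frozenset({"HK", "PFK", "PYK"}),
    "PPP": frozenset({"G6PD", "6PGD", "RPI"}),
    "ED": frozenset({"G6PD", "EDD", "KDGP"}),
}


@dataclass(frozen=True)
class KeywordRuleset:
    """Gate terms, family tokens and enzyme search terms for the screen."""

    gate_terms: frozenset[str] = frozenset({"sugar", "transporter"})
    subtype_tokens: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_TOKENS)
    )
    enzyme_terms: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_ENZYME_TERMS)
    )
    per_occurrence: bool = False  # count token occurrences, not features

    def __post_init__(self) -> None:
        if set(self.subtype_tokens) != set(TRANSPORTER_CATEGORIES):
            raise ValueError(
                f"subtype categories must be exactly {set(TRANSPORTER_CATEGORIES)}"
            )
        for cat, toks in self.subtype_tokens.items():
            if not toks:
                raise ValueError(f"empty token list for category {cat}")
        for enz, terms in self.enzyme_terms.items():
            if not terms:
                raise ValueError(f"empty term list for enzyme {enz}")

    def _token_pattern(self, token: str) -> re.Pattern:
        if token.isupper() and token.isalpha():
            # abbreviation: case-sensitive, word-bounded
            return re.compile(rf"\b{re.escape(token)}\b")
        return re.compile(re.escape(token), re.IGNORECASE)

    def gate_passes(self, product: str) -> bool:
        low = product.lower()
        return all(term.lower() in low for term in self.gate_terms)

    def subtype_hits(self, product: str) -> dict[str, int]:
        """Token hit count per family for one product (no gate applied)."""
        hits = {}
        for cat in TRANSPORTER_CATEGORIES:
            n = 0
            for tok in self.subtype_tokens[cat]:
                n += len(self._token_pattern(tok).findall(product))
            hits[cat] = n
        return hits


@dataclass(frozen=True)
class TransporterCensus:
    genome_id: str
    abc_count: int
    pts_count: int
    mfs_count: int

    def __post_init__(self) -> None:
        if min(self.abc_count, self.pts_count, self.mfs_count) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total_sugar_transporters(self) -> int:
        return self.abc_count + self.pts_count + self.mfs_count


@dataclass(frozen=True)
class EnzymePresence:
    genome_id: str
    presence: Mapping[str, int]

    def __post_init__(self) -> None:
        bad = {e: v for e, v in self.presence.items() if v not in (0, 1)}
        if bad:
            raise ValueError(f"presence values must be binary, got {bad}")


@dataclass(frozen=True)
class PathwayDefinition:
    pathway_id: str
    required_enzymes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.required_enzymes:
            raise ValueError("required_enzymes must be non-empty")


def default_pathway_definitions() -> list[PathwayDefinition]:
    return [PathwayDefinition(pid, req) for pid, req in DEFAULT_PATHWAYS.items()]


def census_transporters(
    annotation: GenomeAnnotation, rules: KeywordRuleset | None = None
) -> TransporterCensus:
    """Count sugar transporters per family in one genome annotation.

    A feature contributes to a family iff its product passes the gate
    (contains every gate term) and contains at least one family token.
    """
    rules = rules or KeywordRuleset()
    counts = {cat: 0 for cat in TRANSPORTER_CATEGORIES}
    for feat in annotation.features:
        if not rules.gate_passes(feat.product):
            continue
        hits = rules.subtype_hits(feat.product)
        for cat, n in hits.items():
            if n > 0:
                counts[cat] += n if rules.per_occurrence else 1
    return TransporterCensus(
        genome_id=annotation.genome_id,
        abc_count=counts["ABC"],
        pts_count=counts["PTS"],
        mfs_count=counts["MFS"],
    )


def screen_enzymes(
    annotation: GenomeAnnotation, rules: KeywordRuleset | None = None
) -> EnzymePresence:
    """Flag each configured glycolytic enzyme present in the annotation.

    An enzyme is present iff any feature's product or gene name matches
    any of its search terms, case-insensitively.
    """
    rules = rules or KeywordRuleset()
    presence = {enz: 0 for enz in rules.enzyme_terms}
    for feat in annotation.features:
        haystacks = [feat.product.lower()]
        if feat.gene_name:
            haystacks.append(feat.gene_name.lower())
        for enz, terms in rules.enzyme_terms.items():
            if presence[enz]:
                continue
            if any(t.lower() in h for t in terms for h in haystacks):
                presence[enz] = 1
    return EnzymePresence(genome_id=annotation.genome_id, presence=presence)


def pathway_complete(presence: EnzymePresence, definition: PathwayDefinition) -> int:
    """1 iff every enzyme required by the pathway is present.

    Only complete pathways are treated as functional downstream.
    """
    missing = definition.required_enzymes - set(presence.presence)
    if missing:
        raise KeyError(
            f"pathway {definition.pathway_id} requires enzymes absent from the "
            f"configured screen: {sorted(missing)}"
        )
    return int(all(presence.presence[e] == 1 for e in definition.required_enzymes))


def _stable_key(k: str) -> int:
    import hashlib

    return int.from_bytes(hashlib.sha256(k.encode()).digest()[:4], "little")


def _child_rng(seed: int, *key: str) -> np.random.Generator:
    # process-independent child streams: SeedSequence keyed by a stable
    # digest of the label (python's hash() is salted per process)
    ss = np.random.SeedSequence(seed, spawn_key=tuple(_stable_key(k) for k in key))
    return np.random.default_rng(ss)


def select_species(
    genomes: pd.DataFrame,
    top_k: int = 20,
    per_species_cap: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Pick the study genome set: top species per phylum, capped subsample.

    Parameters
    ----------
    genomes:
        DataFrame with columns ``genome_id``, ``species``, ``phylum``.
    top_k:
        Species retained per phylum, ranked by available genome count
        (descending; ties broken lexicographically by species name).
    per_species_cap:
        Genomes sampled per retained species, without replacement.

    Returns the selected rows (copy), sorted by phylum/species/genome_id.
    Sampling is reproducible under ``seed`` and independent per species.
    """
    required = {"genome_id", "species", "phylum"}
    if missing := required - set(genomes.columns):
        raise ValueError(f"genome table missing columns {sorted(missing)}")
    pieces = []
    for phylum, sub in genomes.groupby("phylum", sort=True):
        counts = (
            sub.groupby("species")["genome_id"]
            .nunique()
            .reset_index(name="n")
            .sort_values(["n", "species"], ascending=[False, True])
        )
        if counts.empty:
            logger.warning("phylum %s has no species; skipping", phylum)
            continue
        keep = counts["species"].head(top_k)
        for sp in keep:
            ids = sorted(sub.loc[sub["species"] == sp, "genome_id"].unique())
            k = min(per_species_cap, len(ids))
            rng = _child_rng(seed, phylum, sp)
            chosen = sorted(rng.choice(ids, size=k, replace=False))
            pieces.append(
                pd.DataFrame({"genome_id": chosen, "species": sp, "phylum": phylum})
            )
    if not pieces:
        return pd.DataFrame(columns=["genome_id", "species", "phylum"])
    out = pd.concat(pieces, ignore_index=True)
    return out.sort_values(["phylum", "species", "genome_id"], ignore_index=True)


@dataclass(frozen=True)
class GenusCensus:
    genus: str
    n_genomes_used: int
    mean_abc: float
    mean_pts: float
    mean_mfs: float

    @property
    def mean_total(self) -> float:
        return self.mean_abc + self.mean_pts + self.mean_mfs


def genus_mean_census(
    censuses: Iterable[TransporterCensus],
    genus_of: Mapping[str, str],
    cap: int = 100,
    seed: int = 0,
) -> list[GenusCensus]:
    """Average transporter counts per genus over a capped genome subsample.

    ``genus_of`` maps genome_id to genus.  Per genus at most ``cap``
    genomes are used (sampled without replacement, seeded); the mean of
    each family count approximates the genus-typical repertoire.
    """
    by_genus: dict[str, list[TransporterCensus]] = {}
    for c in censuses:
        try:
            g = genus_of[c.genome_id]
        except KeyError:
            raise KeyError(f"no genus label for genome {c.genome_id}") from None
        by_genus.setdefault(g, []).append(c)

    out: list[GenusCensus] = []
    for genus in sorted(by_genus):
        group = sorted(by_genus[genus], key=lambda c: c.genome_id)
        if not group:
            logger.warning("genus %s has zero genomes; excluded", genus)
            continue
        if len(group) > cap:
            rng = _child_rng(seed, "genus", genus)
            idx = sorted(rng.choice(len(group), size=cap, replace=False))
            group = [group[i] for i in idx]
        abc = float(np.mean([c.abc_count for c in group]))
        pts = float(np.mean([c.pts_count for c in group]))
        mfs = float(np.mean([c.mfs_count for c in group]))
        out.append(GenusCensus(genus, len(group), abc, pts, mfs))
    return out


def census_table(censuses: Iterable[TransporterCensus]) -> pd.DataFrame:
    """Genome-level census as a tidy table (stable column order)."""
    rows = [
        {
            "genome_id": c.genome_id,
            "abc": c.abc_count,
            "pts": c.pts_count,
            "mfs": c.mfs_count,
            "total": c.total_sugar_transporters,
        }
        for c in censuses
    ]
    return pd.DataFrame(rows, columns=["genome_id", "abc", "pts", "mfs", "total"])


def genus_census_table(censuses: Iterable[GenusCensus]) -> pd.DataFrame:
    rows = [
        {
            "genus": c.genus,
            "abc": c.mean_abc,
            "pts": c.mean_pts,
            "mfs": c.mean_mfs,
            "total": c.mean_total,
            "n_genomes_used": c.n_genomes_used,
        }
        for c in censuses
    ]
    return pd.DataFrame(
        rows, columns=["genus", "abc", "pts", "mfs", "total", "n_genomes_used"]
    )
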