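"""Taxa-to-PFT conversion and arboreal-pollen (AP) percentages.

Pollen taxa are grouped into plant functional types (PFTs) by habit,
phenology, leaf form and climatic range; assemblages are scored per PFT with
the biomisation-style affinity score

    score(PFT) = sum over member taxa of sqrt(max(0, p_taxon - theta))

where p_taxon is the taxon percentage and theta a small threshold (default
0.5 %) suppressing trace occurrences.  Analog matching downstream operates on
the normalized PFT vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .data_io import PollenSample, _normalize_taxon

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.5  # percent


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class PFTDictionary:
    """Mapping taxon -> eligible PFTs plus growth-form flags.

    Taxon names are matched case-insensitively after whitespace
    normalization.  A taxon eligible for several PFTs is *ambiguous*: its
    mass is resolved at scoring time by the context rule (see
    :func:`taxa_to_pft`).  The arboreal / dwarf-shrub / vine flags feed the
    AP sum; dwarf shrubs and vines are excluded from AP even when woody.
    """

    taxon_to_pfts: Mapping[str, tuple[str, ...]]
    arboreal: frozenset[str]
    dwarf_shrub: frozenset[str] = frozenset()
    vine: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.taxon_to_pfts:
            raise ConfigurationError("empty PFT dictionary")
        for t, pfts in self.taxon_to_pfts.items():
            if len(pfts) == 0:
                raise ConfigurationError(f"taxon {t!r} maps to no PFT; mark it unassigned by omission")

    @property
    def pfts(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for pfts in self.taxon_to_pfts.values():
            for p in pfts:
                seen.setdefault(p)
        return tuple(seen)

    def lookup(self, taxon: str) -> tuple[str, ...]:
        return self.taxon_to_pfts.get(_normalize_taxon(taxon), ())

    def is_arboreal(self, taxon: str) -> bool:
        t = _normalize_taxon(taxon)
        return t in self.arboreal and t not in self.dwarf_shrub and t not in self.vine

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PFTDictionary":
        """Build from a table with columns taxon, pfts (semicolon list),
        arboreal, dwarf_shrub, vine (0/1)."""
        required = {"taxon", "pfts"}
        if not required <= set(df.columns):
            raise ConfigurationError(f"dictionary table needs columns {sorted(required)}")
        mapping: dict[str, tuple[str, ...]] = {}
        arb, dwarf, vine = set(), set(), set()
        for _, row in df.iterrows():
            t = _normalize_taxon(row["taxon"])
            pfts = tuple(p.strip() for p in str(row["pfts"]).split(";") if p.strip())
            if pfts:
                mapping[t] = pfts
            if row.get("arboreal", 0):
                arb.add(t)
            if row.get("dwarf_shrub", 0):
                dwarf.add(t)
            if row.get("vine", 0):
                vine.add(t)
        return cls(mapping, frozenset(arb), frozenset(dwarf), frozenset(vine))

    @classmethod
    def from_table(cls, path: str | Path) -> "PFTDictionary":
        return cls.from_frame(pd.read_csv(path, sep=None, engine="python"))


def synthetic_dictionary() -> PFTDictionary:
    """A small 8-taxon / 5-PFT dictionary for synthetic worlds and tests.

    *Betula* is deliberately ambiguous (boreal summer-green tree vs
    arctic-alpine shrub) to exercise the context-resolution rule.
    """
    return PFTDictionary(
        taxon_to_pfts={
            "pinus": ("needleleaf_evergreen",),
            "picea": ("needleleaf_evergreen",),
            "quercus": ("temperate_summergreen",),
            "corylus": ("temperate_summergreen",),
            "betula": ("boreal_summergreen", "arctic_alpine_shrub"),
            "betula nana": ("arctic_alpine_shrub",),
            "poaceae": ("herb",),
            "artemisia": ("herb",),
        },
        arboreal=frozenset({"pinus", "picea", "quercus", "corylus", "betula"}),
        dwarf_shrub=frozenset({"betula nana"}),
        vine=frozenset(),
    )


@dataclass
class PFTVector:
    """Per-PFT affinity scores of one assemblage."""

    pfts: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if (self.scores < 0).any():
            raise ValueError("PFT scores must be non-negative")

    @property
    def normalized(self) -> np.ndarray:
        total = self.scores.sum()
        if total <= 0:
            return np.zeros_like(self.scores)
        return self.scores / total

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=list(self.pfts))


def _score_contribution(p: float, theta: float) -> float:
    return float(np.sqrt(max(0.0, p - theta)))


def taxa_to_pft(
    sample: PollenSample | Mapping[str, float],
    dictionary: PFTDictionary,
    threshold: float = DEFAULT_THRESHOLD,
) -> PFTVector:
    """Score an assemblage against the PFT dictionary.

    Unambiguous taxa contribute sqrt(max(0, p - theta)) to their PFT.  A
    taxon eligible for several PFTs is assigned wholly to the eligible PFT
    with the larger score computed from the *other* taxa (ties split
    equally), mirroring the floristic-context dependence of ambiguous taxa
    such as *Betula*.
    """
    percentages = sample.percentages if isinstance(sample, PollenSample) else sample
    pfts = dictionary.pfts
    index = {p: i for i, p in enumerate(pfts)}
    base = np.zeros(len(pfts))
    ambiguous: list[tuple[str, float, tuple[str, ...]]] = []
    for taxon, pct in percentages.items():
        eligible = dictionary.lookup(taxon)
        if not eligible:
            if pct > 0:
                logger.debug("taxon %r unassigned to any PFT", taxon)
            continue
        contrib = _score_contribution(pct, threshold)
        if contrib == 0.0:
            continue
        if len(eligible) == 1:
            base[index[eligible[0]]] += contrib
        else:
            ambiguous.append((taxon, contrib, eligible))

    scores = base.copy()
    for taxon, contrib, eligible in ambiguous:
        # Context score for each candidate PFT: contributions of all *other*
        # taxa, including other ambiguous taxa counted at full eligibility.
        context = base.copy()
        for other, oc, oe in ambiguous:
            if other == taxon:
                continue
            for p in oe:
                context[index[p]] += oc
        cand = np.array([context[index[p]] for p in eligible])
        best = np.flatnonzero(cand == cand.max())
        share = contrib / len(best)
        for b in best:
            scores[index[eligible[b]]] += share
    return PFTVector(pfts=pfts, scores=scores)


def ap_percentage(
    sample: PollenSample | Mapping[str, float],
    dictionary: PFTDictionary,
) -> float:
    """Arboreal-pollen percentage: summed woody-taxon percentages, excluding
    dwarf shrubs and vines.  Taxa without flags count as non-arboreal."""
    percentages = sample.percentages if isinstance(sample, PollenSample) else sample
    ap = 0.0
    for taxon, pct in percentages.items():
        t = _normalize_taxon(taxon)
        if t not in dictionary.arboreal and t not in dictionary.dwarf_shrub and t not in dictionary.vine:
            if pct > 0 and not dictionary.lookup(taxon):
                logger.debug("unflagged taxon %r counted as non-arboreal", taxon)
        if dictionary.is_arboreal(taxon):
            ap += pct
    return float(min(100.0, max(0.0, ap)))
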