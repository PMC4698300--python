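"""Enrichment of a curated disease-gene panel among prioritized candidates.

With N genes retrieved from one CNV type, K of them in the panel, n
prioritized candidates and k panel genes among the candidates, fold
enrichment is (k/n)/(K/N) and significance is the upper tail of
Hypergeometric(N, K, n). The default tail is strict, P(X > k) — the
convention of R's ``phyper(k, K, N-K, n, lower.tail=FALSE)`` that published
CNV-enrichment tables in this literature use; the inclusive tail P(X >= k)
is available via ``tail="ge"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from scipy.stats import hypergeom

from .errors import ValidationError


@dataclass
class GenePanel:
    """Disease-gene panel; categories per symbol subset of {non_syndromic, syndromic}."""

    categories: dict[str, frozenset[str]]
    aliases: dict[str, str] | None = None  # alias (upper) -> canonical symbol

    def __post_init__(self):
        if not self.categories:
            raise ValidationError("gene panel is empty")
        self._canon = {s.upper(): s for s in self.categories}
        for alias, target in (self.aliases or {}).items():
            self._canon[alias.upper()] = target

    @property
    def symbols(self) -> set[str]:
        return set(self.categories)

    def resolve(self, symbol: str) -> str | None:
        """Canonical panel symbol for ``symbol`` (case-insensitive, alias-aware)."""
        return self._canon.get(symbol.upper())


def read_panel(source, alias_source=None) -> GenePanel:
    """Panel TSV ``symbol  category`` (category in {non_syndromic, syndromic, both});
    optional alias TSV ``alias  symbol``."""
    import pandas as pd

    df = pd.read_csv(source, sep="\t")
    cats: dict[str, frozenset[str]] = {}
    for r in df.itertuples():
        c = {"both": frozenset({"non_syndromic", "syndromic"})}.get(
            r.category, frozenset({r.category})
        )
        cats[r.symbol] = c
    aliases = None
    if alias_source is not None:
        adf = pd.read_csv(alias_source, sep="\t")
        aliases = {r.alias: r.symbol for r in adf.itertuples()}
    return GenePanel(cats, aliases)


@dataclass
class EnrichmentResult:
    N: int
    K: int
    n: int
    k: int
    fold: float
    p: float
    panel_hits: tuple[str, ...] = ()


def fold_enrichment(N: int, K: int, n: int, k: int, tail: str = "gt") -> EnrichmentResult:
    """Fold enrichment and hypergeometric upper-tail p (see module docstring)."""
    if not (0 < n <= N):
        raise ValidationError("need 0 < n <= N")
    if not (0 <= K <= N):
        raise ValidationError("need 0 <= K <= N")
    if not (0 <= k <= min(K, n)):
        raise ValidationError("need 0 <= k <= min(K, n)")
    if K == 0:
        if k > 0:
            raise ValidationError("k > 0 with an empty panel in the universe")
        return EnrichmentResult(N, K, n, k, 0.0, 1.0)
    fold = (k / n) / (K / N)
    if tail == "gt":
        p = float(hypergeom.sf(k, N, K, n))
    elif tail == "ge":
        p = float(hypergeom.sf(k - 1, N, K, n))
    else:
        raise ValidationError(f"unknown tail {tail!r}")
    if k == 0 and tail == "ge":
        p = 1.0
    return EnrichmentResult(N, K, n, k, fold, min(p, 1.0))


def panel_intersection(
    candidates: Sequence[str], panel: GenePanel, universe: Sequence[str]
) -> tuple[int, int, int, int, list[str]]:
    """(N, K, n, k) plus the named panel genes among the candidates.

    ``universe`` is every gene retrieved from the relevant CNV set before
    prioritization; candidates must be a subset of it.
    """
    uni = list(dict.fromkeys(universe))
    cand = list(dict.fromkeys(candidates))
    missing = [c for c in cand if c not in set(uni)]
    if missing:
        raise ValidationError(f"candidates not in universe (pipeline inconsistency): {missing}")
    K_hits = [g for g in uni if panel.resolve(g) is not None]
    k_hits = [g for g in cand if panel.resolve(g) is not None]
    return len(uni), len(K_hits), len(cand), len(k_hits), k_hits
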