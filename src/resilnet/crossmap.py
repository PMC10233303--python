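"""Cross-species projection of treatment-responsive proteins onto modules.

Rat symbols from the treatment differential-expression analysis are mapped
to human symbols through a static ortholog table, and the mapped lists
(all / up / down) are tested for overrepresentation in each human
consensus module with one-tailed Fisher exact tests, Benjamini-Hochberg
corrected per list, star-coded at q < 0.05 / < 0.01 / < 0.005.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .enrichment import GeneSetCollection, bh_adjust, fisher_enrichment

__all__ = ["load_ortholog_map", "map_symbols", "module_overlap_test", "star_code"]


def load_ortholog_map(table: pd.DataFrame) -> dict[str, str]:
    """Rat -> human symbol dict from a two-column table.

    Many-to-one collisions are resolved by first occurrence (with a
    recorded warning attribute); empty symbols are rejected.
    """
    out: dict[str, str] = {}
    collisions = []
    for rat, human in zip(table.iloc[:, 0], table.iloc[:, 1]):
        rat, human = str(rat).strip(), str(human).strip()
        if not rat or not human:
            raise ValueError("ortholog map contains empty symbols")
        if rat in out:
            collisions.append(rat)
            continue
        out[rat] = human.upper()
    if collisions:
        import warnings

        warnings.warn(f"{len(collisions)} duplicate rat symbols kept first mapping")
    return out


def map_symbols(
    symbols: Iterable[str], mapping: Mapping[str, str]
) -> tuple[list[str], int]:
    """Map rat symbols to uppercased human symbols.

    Deduplicates while preserving first occurrence; returns the mapped
    list and the count of unmapped inputs.
    """
    if not mapping:
        raise ValueError("empty ortholog map")
    mapped: list[str] = []
    seen = set()
    unmapped = 0
    for s in symbols:
        s = str(s)
        if s in mapping:
            h = mapping[s].upper()
        elif s.upper() == s and s in set(mapping.values()):
            h = s  # already-human symbols pass through an identity check
        else:
            unmapped += 1
            continue
        if h not in seen:
            seen.add(h)
            mapped.append(h)
    return mapped, unmapped


def star_code(q: float) -> str:
    if q < 0.005:
        return "***"
    if q < 0.01:
        return "**"
    if q < 0.05:
        return "*"
    return ""


def module_overlap_test(
    lists: Mapping[str, Iterable[str]],
    modules: GeneSetCollection,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Fisher overlap of each mapped list with each module.

    ``universe`` defaults to the conservative intersection of the union
    of the query lists with the module universe; BH correction is applied
    across modules within each list.  Returns a long frame (list, module,
    overlap, odds, fold, p, q, stars).
    """
    all_query = set()
    for syms in lists.values():
        all_query |= {str(s).upper() for s in syms}
    if universe is None:
        uni = all_query & set(modules.universe)
    else:
        uni = {str(s).upper() for s in universe}
    mods = modules.harmonized(uni)
    rows = []
    for lname, syms in lists.items():
        query = {str(s).upper() for s in syms} & uni
        ps = []
        for mname, mset in mods.sets.items():
            odds, p, fold = fisher_enrichment(query, mset, uni)
            overlap = len(query & mset)
            rows.append(dict(list=lname, module=mname, overlap=overlap,
                             odds=odds, fold=fold, p=p))
            ps.append(p)
        qs = bh_adjust(ps)
        for off, q in enumerate(qs):
            rows[len(rows) - len(qs) + off]["q"] = float(q)
    out = pd.DataFrame(rows)
    out["stars"] = out["q"].map(star_code)
    return out
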