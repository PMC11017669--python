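"""Metabolite-set over-representation analysis (ORA).

Given a query set of metabolites (e.g., those causally associated with a
trait) and a pathway library in GMT format (SMPDB/KEGG-style), each pathway
is scored by the upper-tail hypergeometric probability of observing at least
the seen overlap between the query and the pathway's members, drawn from the
background universe.

Metabolite naming differs across libraries ("Oxoglutaric acid" vs
"2-Oxoglutarate"), so matching is case-insensitive with punctuation and
whitespace stripped, and an explicit synonym map can be supplied.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

_PUNCT = re.compile(r"[\s\-_,;:()\[\]'\"./]+")


def normalize_name(name: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Canonical form: lowercase, punctuation/whitespace removed, then mapped
    through the synonym table (which is itself matched on normalized keys)."""
    key = _PUNCT.sub("", name.strip().lower())
    if synonyms and key in synonyms:
        return synonyms[key]
    return key


def read_synonyms(path: str | Path) -> dict[str, str]:
    """Two-column delimited file: alias <tab> canonical name."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, names=["alias", "canonical"])
    return {
        normalize_name(a): normalize_name(c)
        for a, c in zip(df["alias"], df["canonical"])
    }


@dataclasses.dataclass
class PathwayLibrary:
    """Named collection of metabolite sets with a background universe."""

    name: str
    sets: dict[str, set[str]]
    background: set[str]

    def __post_init__(self):
        for pname, members in self.sets.items():
            if not members:
                raise ValueError(f"empty pathway set: {pname}")
            if not members <= self.background:
                raise ValueError(f"pathway {pname} has members outside the background")

    @property
    def n_sets(self) -> int:
        return len(self.sets)


def read_gmt(
    path: str | Path,
    name: str | None = None,
    background: Iterable[str] | None = None,
    synonyms: Mapping[str, str] | None = None,
) -> PathwayLibrary:
    """Parse a GMT file (pathway, description, members...).

    Member names are normalized; duplicates within a line are collapsed.
    The background defaults to the union of all sets.
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >=1 member")
        pname = parts[0].strip()
        members = {normalize_name(m, synonyms) for m in parts[2:] if m.strip()}
        if not members:
            raise ValueError(f"{path}:{lineno}: pathway {pname!r} has no members")
        sets[pname] = members
    if not sets:
        raise ValueError(f"{path}: no pathway sets found")
    if background is not None:
        bg = {normalize_name(m, synonyms) for m in background}
    else:
        bg = set().union(*sets.values())
    return PathwayLibrary(name or path.stem, sets, bg)


def ora(
    query: Iterable[str],
    lib: PathwayLibrary,
    synonyms: Mapping[str, str] | None = None,
    drop_log: list | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` against each pathway.

    With background size N, pathway size K, effective query size n and
    overlap k, the p-value is P(X >= k) for X ~ Hypergeometric(N, K, n);
    k = 0 gives p = 1.  Query members outside the background are logged and
    dropped.  Rows sorted ascending by p-value.
    """
    q_norm = {normalize_name(m, synonyms) for m in query}
    if not q_norm:
        raise ValueError("empty query")
    outside = q_norm - lib.background
    if drop_log is not None:
        for m in sorted(outside):
            drop_log.append((m, "not_in_background"))
    q_eff = q_norm & lib.background
    if not q_eff:
        raise ValueError("no query metabolites found in the background")
    N, n = len(lib.background), len(q_eff)
    rows = []
    for pname, members in lib.sets.items():
        K = len(members)
        hits = sorted(q_eff & members)
        k = len(hits)
        # upper tail P(X >= k); sf(k-1) == P(X > k-1)
        pval = 1.0 if k == 0 else float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "pathway_name": pname,
                "library": lib.name,
                "set_size": K,
                "k_overlap": k,
                "hits": ";".join(hits),
                "pval": min(pval, 1.0),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["pval", "pathway_name"], kind="mergesort", ignore_index=True
    )
    return df
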