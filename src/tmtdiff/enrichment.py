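"""Over-representation analysis of a selected protein list against GMT sets.

For each gene set the table reports Count (selected members present in
the background), PH (set members in the background — the pathway total),
Percent = 100·Count/PH, a one-sided hypergeometric p-value (Fisher
upper tail, or the EASE variant with the count reduced by one) and a
Benjamini–Hochberg q across sets.  Identifier matching is
case-insensitive on gene symbols.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = ["GeneSetCollection", "read_gmt", "write_gmt", "ora"]


@dataclass
class GeneSetCollection:
    """Named gene sets with (upper-cased) member symbols."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def add(self, name: str, members, description: str = "") -> None:
        if name in self.sets:
            raise InputError(f"duplicate gene-set name: {name!r}")
        members = [str(m).upper() for m in members]
        unique = set(members)
        if len(unique) < len(members):
            logger.warning("set %r: %d duplicate members removed", name, len(members) - len(unique))
        if not unique:
            raise InputError(f"gene set {name!r} has no members")
        self.sets[name] = unique
        self.descriptions[name] = description


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (name, description, members... per tab-separated line)."""
    coll = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
            coll.add(parts[0], parts[2:], description=parts[1])
    return coll


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in coll:
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def ora(
    selected,
    background,
    sets: GeneSetCollection,
    method: str = "fisher",
    ph_in_background: bool = True,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` within ``background``.

    Parameters
    ----------
    selected, background
        protein/gene identifiers; ``selected`` must be a subset of
        ``background`` (the tested universe).
    method
        ``"fisher"`` for the plain hypergeometric upper tail
        P(X >= count), ``"ease"`` for the conservative variant that
        discounts one selected member.
    ph_in_background
        when False, PH is the raw set size rather than the set
        restricted to the background (display convention only; the
        p-value always uses the background-restricted count).

    Returns rows sorted by p with columns term, count, PH, percent
    (one decimal), p and q_bh.
    """
    if method not in ("fisher", "ease"):
        raise InputError(f"method must be 'fisher' or 'ease', got {method!r}")
    sel = {str(s).upper() for s in selected}
    bg = {str(s).upper() for s in background}
    stray = sel - bg
    if stray:
        raise InputError(f"selected ids missing from background: {sorted(stray)[:5]}")
    N, n = len(bg), len(sel)
    rows = []
    for name, members in sets:
        in_bg = members & bg
        K = len(in_bg)
        k = len(in_bg & sel)
        ph = K if ph_in_background else len(members)
        if K == 0:
            continue
        shift = 1 if method == "fisher" else 2
        # P(X >= k) for fisher, P(X >= k-1) for ease; sf(<0) is 1 as wanted
        p = min(max(float(stats.hypergeom.sf(k - shift, N, K, n)), 0.0), 1.0)
        percent = round(100.0 * k / ph, 1) if ph else 0.0
        rows.append((name, k, ph, percent, p))
    out = pd.DataFrame(rows, columns=["term", "count", "PH", "percent", "p"])
    if len(out):
        out["q_bh"] = multipletests(out["p"], method="fdr_bh")[1]
        out = out.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    else:
        out["q_bh"] = pd.Series(dtype=float)
    return out
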