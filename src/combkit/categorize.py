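"""Discretize domain and behavior scores into H/M/L transaction encoding.

A respondent's domain score is the arithmetic mean of the domain's item
responses; scores are cut as: score < 3 -> L, 3 <= score < 4 -> M,
score >= 4 -> H.  Each respondent then contributes one ``DOMAIN=LEVEL``
element per domain and per behavior, forming a market-basket transaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .instrument import InstrumentSpec

logger = logging.getLogger(__name__)

LEVELS = ("L", "M", "H")


class CategorizeError(ValueError):
    pass


def domain_score(data: pd.DataFrame, items: list[str]) -> pd.Series:
    """Mean item score per respondent; respondents with a missing item are dropped."""
    if not items:
        raise CategorizeError("empty domain")
    sub = data[list(items)]
    complete = sub.dropna()
    dropped = len(sub) - len(complete)
    if dropped:
        logger.info("domain %s: dropped %d incomplete respondents", items, dropped)
    return complete.astype(float).mean(axis=1)


def categorize_score(score) -> str | np.ndarray:
    """Map a mean score in [1, 5] to L/M/H (vectorized over arrays)."""
    arr = np.asarray(score, dtype=float)
    if np.any(arr < 1) or np.any(arr > 5):
        raise CategorizeError("score outside [1, 5]")
    out = np.where(arr < 3, "L", np.where(arr < 4, "M", "H"))
    return str(out[()]) if out.ndim == 0 else out


@dataclass
class TransactionTable:
    """One H/M/L basket per respondent over domains and behaviors."""

    transactions: list[frozenset[str]]
    respondent_ids: list
    dropped_ids: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.transactions)

    @property
    def vocabulary(self) -> set[str]:
        return set().union(*self.transactions) if self.transactions else set()

    def to_long_frame(self) -> pd.DataFrame:
        rows = [
            {"respondent": rid, "element": el}
            for rid, t in zip(self.respondent_ids, self.transactions)
            for el in sorted(t)
        ]
        return pd.DataFrame(rows)

    def write_basket(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for t in self.transactions:
                fh.write(",".join(sorted(t)) + "\n")

    @classmethod
    def read_basket(cls, path) -> "TransactionTable":
        transactions = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    transactions.append(frozenset(line.split(",")))
        return cls(transactions=transactions,
                   respondent_ids=list(range(1, len(transactions) + 1)))


def domain_score_table(
    data: pd.DataFrame, spec: InstrumentSpec, retained_items: list[str] | None = None
) -> pd.DataFrame:
    """Respondent x (domain scores + behavior items) table.

    When ``retained_items`` is given, domain means use only those items
    (post-screening); domains left with no retained items raise.
    """
    cols: dict[str, pd.Series] = {}
    for dom in spec.non_behavior_domains:
        items = [
            i for i in spec.items[dom]
            if retained_items is None or i in retained_items
        ]
        if not items:
            raise CategorizeError(f"domain {dom!r} has no retained items")
        cols[dom] = domain_score(data, items)
    for beh in spec.behavior_items:
        cols[beh] = data[beh].astype(float)
    return pd.DataFrame(cols).dropna()


def build_transactions(
    data: pd.DataFrame,
    spec: InstrumentSpec,
    retained_items: list[str] | None = None,
) -> TransactionTable:
    """Categorize every domain and behavior score into one element each.

    Respondents with missing items are dropped (and enumerated); every kept
    respondent contributes exactly one level per domain/behavior.
    """
    scores = domain_score_table(data, spec, retained_items)
    dropped = [rid for rid in data.index if rid not in scores.index]
    if dropped:
        logger.info("transactions: dropped incomplete respondents %s", dropped)
    transactions = []
    for _, row in scores.iterrows():
        transactions.append(
            frozenset(f"{col}={categorize_score(val)}" for col, val in row.items())
        )
    return TransactionTable(
        transactions=transactions,
        respondent_ids=list(scores.index),
        dropped_ids=dropped,
    )


def recode_levels(
    table: TransactionTable, recode_map: list[tuple[str, str, str]]
) -> TransactionTable:
    """Relabel levels of specific domains, e.g. ``[("VAL", "M", "L")]``.

    Unknown domains raise; recoding a level absent from the table is a
    logged no-op for that rule.
    """
    vocab_domains = {el.split("=")[0] for el in table.vocabulary}
    for domain, frm, to in recode_map:
        if domain not in vocab_domains:
            raise CategorizeError(f"unknown element {domain!r} in recode map")
        if frm not in LEVELS or to not in LEVELS:
            raise CategorizeError(f"unknown level in recode rule {(domain, frm, to)}")
    new_transactions = []
    changes = {tuple(r): 0 for r in recode_map}
    for t in table.transactions:
        items = set(t)
        for domain, frm, to in recode_map:
            src = f"{domain}={frm}"
            if src in items:
                items.discard(src)
                items.add(f"{domain}={to}")
                changes[(domain, frm, to)] += 1
    # rebuild in one pass so multiple rules on one domain do not chain
        new_transactions.append(frozenset(items))
    for rule, count in changes.items():
        logger.info("recode %s->%s for %s: %d transactions changed",
                    rule[1], rule[2], rule[0], count)
    return TransactionTable(
        transactions=new_transactions,
        respondent_ids=list(table.respondent_ids),
        dropped_ids=list(table.dropped_ids),
    )
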