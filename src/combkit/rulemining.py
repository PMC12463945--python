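"""Apriori frequent-itemset mining and behavior-partitioned rule analysis.

Measures over a table of N transactions:

    support(Z)        = count(transactions containing Z) / N
    confidence(X->Y)  = support(X u Y) / support(X)
    lift(X->Y)        = confidence(X->Y) / support(Y)

Rules are kept when support and confidence meet their minima and lift
strictly exceeds its threshold, then grouped into behavior x level
partitions; within each partition middle-level (M) antecedent elements are
eliminated (with explicit per-partition exceptions), the top rules by lift
are the "strong" rules, and domain appearance counts across strong rules
profile which determinants co-occur with each behavior level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

from .categorize import TransactionTable

logger = logging.getLogger(__name__)


class RuleMiningError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Apriori
# ---------------------------------------------------------------------------

def apriori_frequent_itemsets(
    table: TransactionTable,
    min_support: float,
    item_filter=None,
    max_len: int | None = None,
) -> dict[frozenset, float]:
    """All itemsets with support >= min_support, by level-wise search.

    Candidate (k+1)-itemsets are joined from frequent k-itemsets sharing a
    (k-1)-prefix and pruned by the anti-monotonicity of support.
    ``item_filter`` (itemset -> bool) can veto candidates, e.g. to cap the
    number of behavior elements per itemset; it must itself be
    anti-monotone to keep the search exact.
    """
    if not 0 < min_support <= 1:
        raise RuleMiningError("min_support must be in (0, 1]")
    if table.n == 0:
        raise RuleMiningError("empty transaction table")
    n = table.n
    transactions = table.transactions

    counts: dict[str, int] = {}
    for t in transactions:
        for el in t:
            counts[el] = counts.get(el, 0) + 1
    threshold = min_support * n
    frequent: dict[frozenset, float] = {}
    level = []
    for el, c in counts.items():
        if c >= threshold:
            iset = frozenset((el,))
            if item_filter is None or item_filter(iset):
                frequent[iset] = c / n
                level.append((el,))
    level = sorted(level)
    k = 1
    while level and (max_len is None or k < max_len):
        candidates = set()
        level_set = {frozenset(t) for t in level}
        for i in range(len(level)):
            for j in range(i + 1, len(level)):
                a, b = level[i], level[j]
                if a[:-1] != b[:-1]:
                    break  # sorted prefixes: no further joins for a
                cand = tuple(sorted(set(a) | set(b)))
                cset = frozenset(cand)
                if item_filter is not None and not item_filter(cset):
                    continue
                if all(frozenset(cand[:m] + cand[m + 1:]) in level_set
                       for m in range(len(cand))):
                    candidates.add(cand)
        next_level = []
        for cand in sorted(candidates):
            cset = frozenset(cand)
            c = sum(1 for t in transactions if cset <= t)
            if c >= threshold:
                frequent[cset] = c / n
                next_level.append(cand)
        level = sorted(next_level)
        k += 1
    return frequent


# ---------------------------------------------------------------------------
# rule generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset[str]
    consequent: str
    support: float
    confidence: float
    lift: float

    @property
    def partition_key(self) -> str:
        return self.consequent

    def __str__(self) -> str:
        lhs = ", ".join(sorted(self.antecedent))
        return (f"{{{lhs}}} -> {self.consequent} "
                f"(s={self.support:.3f}, c={self.confidence:.3f}, l={self.lift:.2f})")


def generate_rules(
    itemsets: dict[frozenset, float],
    consequents: set[str],
    min_confidence: float = 0.5,
    min_lift: float = 2.0,
    antecedent_universe: set[str] | None = None,
) -> list[AssociationRule]:
    """Rules X -> Y with a single behavior consequent Y.

    Emitted for every frequent itemset containing exactly one element of
    ``consequents``; a rule survives when support and confidence meet their
    minima (support already guaranteed by the frequent set) and lift is
    strictly greater than ``min_lift``.  ``antecedent_universe``, when
    given, restricts which elements may appear on the left-hand side.
    """
    rules = []
    for iset, sup_xy in itemsets.items():
        cons = [el for el in iset if el in consequents]
        if len(cons) != 1:
            continue
        y = cons[0]
        x = iset - {y}
        if not x:
            continue
        if antecedent_universe is not None and not x <= antecedent_universe:
            continue
        sup_x = itemsets.get(x)
        sup_y = itemsets.get(frozenset((y,)))
        if sup_x is None or sup_y is None:
            continue  # X or Y below the support floor: rule cannot qualify
        confidence = sup_xy / sup_x
        lift = confidence / sup_y
        if confidence >= min_confidence and lift > min_lift:
            rules.append(AssociationRule(
                antecedent=x, consequent=y,
                support=sup_xy, confidence=confidence, lift=lift,
            ))
    return rules


# ---------------------------------------------------------------------------
# partitions, strong rules, domain profiling
# ---------------------------------------------------------------------------

@dataclass
class RulePartition:
    key: str                       # e.g. "BEH-1=H"
    rules: list[AssociationRule]
    n_before_middle_filter: int
    exceptions: set[str] = field(default_factory=set)
    strong_rules: list[AssociationRule] = field(default_factory=list)


def _level_of(element: str) -> str:
    return element.rsplit("=", 1)[1]


def _domain_of(element: str) -> str:
    return element.rsplit("=", 1)[0]


def partition_and_filter(
    rules: list[AssociationRule],
    drop_middle: bool = True,
    exceptions: dict[str, set[str]] | None = None,
) -> list[RulePartition]:
    """Group rules by behavior x level; drop M-level content.

    Rules whose consequent is an M level are removed first; then, inside
    each partition, any rule containing an M-level antecedent element is
    eliminated unless that element's domain is in the partition's exception
    set.  Partitions are returned in sorted key order.
    """
    exceptions = exceptions or {}
    known = {r.partition_key for r in rules}
    for key in exceptions:
        if key not in known:
            raise RuleMiningError(f"exception references unknown partition {key!r}")
    groups: dict[str, list[AssociationRule]] = {}
    for rule in rules:
        if _level_of(rule.consequent) == "M":
            continue
        groups.setdefault(rule.partition_key, []).append(rule)
    partitions = []
    for key in sorted(groups):
        pool = groups[key]
        if drop_middle:
            allowed = exceptions.get(key, set())
            kept = [
                r for r in pool
                if all(_level_of(el) != "M" or _domain_of(el) in allowed
                       for el in r.antecedent)
            ]
        else:
            kept = list(pool)
        logger.info("partition %s: %d rules -> %d after middle filter",
                    key, len(pool), len(kept))
        partitions.append(RulePartition(
            key=key, rules=kept, n_before_middle_filter=len(pool),
            exceptions=set(exceptions.get(key, set())),
        ))
    return partitions


def rule_sort_key(rule: AssociationRule):
    return (-rule.lift, -rule.confidence, -rule.support, tuple(sorted(rule.antecedent)))


def top_strong_rules(partition: RulePartition, n: int = 10) -> RulePartition:
    """Retain the top-``n`` rules by lift (ties: confidence, support, lexicographic)."""
    ranked = sorted(partition.rules, key=rule_sort_key)
    if len(ranked) > n and rule_sort_key(ranked[n - 1])[:3] == rule_sort_key(ranked[n])[:3]:
        logger.info("partition %s: tie at the top-%d boundary resolved lexicographically",
                    partition.key, n)
    partition.strong_rules = ranked[:n]
    return partition


@dataclass
class DomainFrequencyProfile:
    partition_key: str
    counts: dict[str, int]
    threshold: int
    flagged: list[str]


def domain_frequency(partition: RulePartition, threshold: int = 5) -> DomainFrequencyProfile:
    """Count each domain's appearances across the strong rules' antecedents."""
    counts: dict[str, int] = {}
    for rule in partition.strong_rules:
        for el in rule.antecedent:
            dom = _domain_of(el)
            counts[dom] = counts.get(dom, 0) + 1
    flagged = sorted(d for d, c in counts.items() if c >= threshold)
    return DomainFrequencyProfile(
        partition_key=partition.key, counts=counts,
        threshold=threshold, flagged=flagged,
    )


def mine_behavior_rules(
    table: TransactionTable,
    behavior_codes: list[str],
    min_support: float = 0.05,
    min_confidence: float = 0.5,
    min_lift: float = 2.0,
    top_n: int = 10,
    frequency_threshold: int = 5,
    drop_middle: bool = True,
    exceptions: dict[str, set[str]] | None = None,
    restrict_antecedents: bool = True,
    max_len: int | None = None,
) -> tuple[list[RulePartition], list[DomainFrequencyProfile]]:
    """End-to-end mining: Apriori -> rules -> partitions -> strong rules -> profile."""
    behavior_elements = {
        f"{b}={lvl}" for b in behavior_codes for lvl in ("L", "M", "H")
    }
    item_filter = None
    if restrict_antecedents:
        def item_filter(iset):  # at most one behavior element per itemset
            return sum(el in behavior_elements for el in iset) <= 1
    itemsets = apriori_frequent_itemsets(
        table, min_support, item_filter=item_filter, max_len=max_len
    )
    universe = None
    if restrict_antecedents:
        universe = {el for el in table.vocabulary if el not in behavior_elements}
    rules = generate_rules(
        itemsets, consequents=behavior_elements,
        min_confidence=min_confidence, min_lift=min_lift,
        antecedent_universe=universe,
    )
    partitions = partition_and_filter(rules, drop_middle=drop_middle,
                                      exceptions=exceptions)
    profiles = []
    for part in partitions:
        top_strong_rules(part, n=top_n)
        profiles.append(domain_frequency(part, threshold=frequency_threshold))
    return partitions, profiles


def rules_to_frame(partitions: list[RulePartition]):
    import pandas as pd

    rows = []
    for part in partitions:
        strong = set(map(id, part.strong_rules))
        for rule in part.rules:
            rows.append({
                "antecedent": "; ".join(sorted(rule.antecedent)),
                "consequent": rule.consequent,
                "support": rule.support,
                "confidence": rule.confidence,
                "lift": rule.lift,
                "partition": part.key,
                "strong": id(rule) in strong,
            })
    return pd.DataFrame(rows)
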