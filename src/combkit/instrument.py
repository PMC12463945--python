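"""Instrument specification: modules, domains, and items of a COM-B questionnaire.

The COM-B framework measures Capability, Opportunity and Motivation as
determinants of a target Behavior.  Each non-Behavior module is a
second-order construct measured through first-order domains (e.g. BR =
behavioral regulation), each domain through >= 3 Likert items.  Behaviors
are single-item outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

MODULE_NAMES = ("Capability", "Motivation", "Opportunity", "Behavior")


class InstrumentError(ValueError):
    """Invalid instrument structure."""


@dataclass(frozen=True)
class InstrumentSpec:
    """Mapping of modules -> domains -> items for one questionnaire.

    Parameters
    ----------
    domains
        Mapping from module name to the ordered list of domain codes it
        contains.  The Behavior module is described by ``behavior_items``
        and must not appear here.
    items
        Mapping from domain code to the ordered list of item codes.
    behavior_items
        Ordered list of single-item outcome behaviors (e.g. ``BEH-1``).
    """

    domains: dict[str, tuple[str, ...]]
    items: dict[str, tuple[str, ...]]
    behavior_items: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "domains", {m: tuple(v) for m, v in self.domains.items()}
        )
        object.__setattr__(
            self, "items", {d: tuple(v) for d, v in self.items.items()}
        )
        object.__setattr__(self, "behavior_items", tuple(self.behavior_items))
        self._validate()

    def _validate(self) -> None:
        for module in self.domains:
            if module not in MODULE_NAMES or module == "Behavior":
                raise InstrumentError(f"unknown module {module!r}")
        declared = [d for doms in self.domains.values() for d in doms]
        if len(set(declared)) != len(declared):
            raise InstrumentError("a domain code appears in more than one module")
        if set(declared) != set(self.items):
            raise InstrumentError("items mapping must cover exactly the declared domains")
        seen: dict[str, str] = {}
        for domain, codes in self.items.items():
            if len(codes) < 3:
                raise InstrumentError(
                    f"domain {domain!r} has {len(codes)} items; a latent domain "
                    "requires at least three"
                )
            for code in codes:
                if code in seen:
                    raise InstrumentError(
                        f"item {code!r} assigned to both {seen[code]!r} and {domain!r}"
                    )
                seen[code] = domain
        for beh in self.behavior_items:
            if beh in seen:
                raise InstrumentError(f"behavior {beh!r} collides with an item code")

    # -- lookups ---------------------------------------------------------

    @property
    def modules(self) -> tuple[str, ...]:
        mods = tuple(self.domains)
        return mods + (("Behavior",) if self.behavior_items else ())

    @property
    def non_behavior_domains(self) -> tuple[str, ...]:
        return tuple(d for doms in self.domains.values() for d in doms)

    @property
    def all_items(self) -> tuple[str, ...]:
        out = [c for d in self.non_behavior_domains for c in self.items[d]]
        out.extend(self.behavior_items)
        return tuple(out)

    def module_of(self, domain: str) -> str:
        if domain in self.behavior_items:
            return "Behavior"
        for module, doms in self.domains.items():
            if domain in doms:
                return module
        raise KeyError(domain)

    def domain_of(self, item: str) -> str:
        if item in self.behavior_items:
            return item  # behaviors are their own single-item domain
        for domain, codes in self.items.items():
            if item in codes:
                return domain
        raise KeyError(item)

    def domain_items(self, domain: str) -> tuple[str, ...]:
        if domain in self.behavior_items:
            return (domain,)
        return self.items[domain]

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "domains": {m: list(v) for m, v in self.domains.items()},
            "items": {d: list(v) for d, v in self.items.items()},
            "behavior_items": list(self.behavior_items),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "InstrumentSpec":
        return cls(
            domains=data["domains"],
            items=data["items"],
            behavior_items=data.get("behavior_items", ()),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "InstrumentSpec":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_instrument() -> InstrumentSpec:
    """The retained 15-domain COM-B instrument with 8 target behaviors.

    Capability: 3 domains x 3 items; Motivation: 7 domains x 3 items;
    Opportunity: the occupational-health-culture domains with
    3 + 5 + 5 + 4 + 4 items; Behavior: 8 single-item outcomes.
    """
    domains = {
        "Capability": ("BR", "DM", "KS"),
        "Motivation": ("SR", "OP", "BCO", "REI", "EM", "INT", "BCA"),
        "Opportunity": ("VAL", "LS", "PN", "PE", "EI"),
    }
    items = {
        "BR": ("BR1", "BR2", "BR4"),
        "DM": ("DM2", "DM4", "DM3"),
        "KS": ("KS4", "KS2", "KS1"),
        "SR": ("SR3", "SR1", "SR2"),
        "OP": ("OP1", "OP2", "OP3"),
        "BCO": ("BCO1", "BCO3", "BCO2"),
        "REI": ("REI3", "REI1", "REI2"),
        "EM": ("EM3", "EM2", "EM1"),
        "INT": ("INT1", "INT2", "INT3"),
        "BCA": ("BCA1", "BCA2", "BCA3"),
        "VAL": ("VAL1", "VAL2", "VAL3"),
        "LS": ("LS1", "LS2", "LS3", "LS4", "LS5"),
        "PN": ("PN1", "PN2", "PN3", "PN4", "PN5"),
        "PE": ("PE1", "PE2", "PE3", "PE4"),
        "EI": ("EI1", "EI2", "EI3", "EI4"),
    }
    behaviors = tuple(f"BEH-{k}" for k in range(1, 9))
    return InstrumentSpec(domains=domains, items=items, behavior_items=behaviors)
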