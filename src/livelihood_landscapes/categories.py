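"""Occupational category lists.

A study fixes one ordered list of occupation categories up front; every
livelihood network built from that study's surveys shares this node set, so
network size is constant across aggregation levels and density/centralization
values are comparable between sites, regions and countries.

The ``none`` category is exclusive: a household that reports no income
activity is coded with ``none`` alone, and ``none`` never co-occurs with a
real occupation (and therefore never carries links).
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Default category labels, in display order.
DEFAULT_LABELS: tuple[str, ...] = (
    "fishing",
    "selling_marine_products",
    "tourism",
    "farming",
    "cash_crops",
    "gleaning",
    "salaried",
    "informal",
    "other",
    "none",
)

NONE_LABEL = "none"


@dataclass(frozen=True)
class CategorySet:
    """A fixed, ordered list of occupation categories for one study.

    Parameters
    ----------
    labels
        Unique identifier strings, in display order.
    exclusive
        Labels that cannot co-occur with any other category in one household
        portfolio (by default ``{"none"}`` when present).
    """

    labels: tuple[str, ...] = DEFAULT_LABELS
    exclusive: frozenset[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("category labels must be unique")
        if self.exclusive is None:
            default = frozenset({NONE_LABEL}) & set(self.labels)
            object.__setattr__(self, "exclusive", default)
        else:
            object.__setattr__(self, "exclusive", frozenset(self.exclusive))
            unknown = self.exclusive - set(self.labels)
            if unknown:
                raise ValueError(f"exclusive labels not in list: {sorted(unknown)}")

    def __contains__(self, label: object) -> bool:
        return label in self.labels

    def __iter__(self):
        return iter(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def active(self) -> tuple[str, ...]:
        """Labels that can participate in links (everything non-exclusive)."""
        return tuple(l for l in self.labels if l not in self.exclusive)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def without_none(self) -> "CategorySet":
        """The same list with the ``none`` category dropped (config switch)."""
        return CategorySet(tuple(l for l in self.labels if l != NONE_LABEL))


DEFAULT_CATEGORIES = CategorySet()
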