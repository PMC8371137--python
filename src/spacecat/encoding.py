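"""Combinatorial dye-code design arithmetic for photoactivatable tagging.

A sample is iteratively stained with photocaged dyes and user-drawn regions
are exposed to near-UV light. A dye uncages in a region when some exposure
at or above its uncaging threshold occurs *after* the dye was stained; dyes
persist in cells once stained, so a later high exposure also uncages
earlier-stained dyes. A region's code is the set of uncaged dyes; the empty
code is background.

With dyes grouped by uncaging threshold, this sequential scheme reaches
``prod_k (n_k + 1) - 1`` distinct non-empty codes over threshold classes of
sizes ``n_k`` — e.g. one slow dye (10 s) plus two fast dyes (0.5 s) yields
five codes, multiplicative in the number of dyes per threshold class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations, product

__all__ = [
    "Stain",
    "Activate",
    "DyeProtocol",
    "RegionCode",
    "ExposurePolicy",
    "YieldAccount",
    "enumerate_codes",
    "max_codes",
    "exposure_limit",
    "expected_yield",
    "five_color_protocol",
]


class ProtocolError(ValueError):
    """A dye protocol violates its invariants."""


@dataclass(frozen=True)
class Stain:
    dye: str


@dataclass(frozen=True)
class Activate:
    region: str
    exposure_seconds: float


@dataclass
class DyeProtocol:
    """Ordered dyes with uncaging thresholds, plus stain/activate events.

    ``dyes`` maps dye name -> uncaging threshold in seconds of near-UV
    exposure; ``events`` is the ordered experimental sequence.
    """

    dyes: dict
    events: list = field(default_factory=list)

    def __post_init__(self):
        for dye, threshold in self.dyes.items():
            if threshold <= 0:
                raise ProtocolError(f"threshold for {dye} must be positive")
        for ev in self.events:
            if isinstance(ev, Stain):
                if ev.dye not in self.dyes:
                    raise ProtocolError(f"Stain of unknown dye {ev.dye!r}")
            elif isinstance(ev, Activate):
                if ev.exposure_seconds < 0:
                    raise ProtocolError(
                        f"negative exposure for region {ev.region!r}"
                    )
            else:
                raise ProtocolError(f"unknown event type {type(ev).__name__}")


@dataclass(frozen=True)
class RegionCode:
    region: str
    code: frozenset


def enumerate_codes(protocol: DyeProtocol):
    """Replay a protocol and return per-region dye codes.

    Returns ``(codes, n_distinct_nonempty)`` where ``codes`` is a list of
    :class:`RegionCode`, one per region in order of first activation.
    """
    stained: list[str] = []
    uncaged: dict[str, set] = {}
    order: list[str] = []
    for ev in protocol.events:
        if isinstance(ev, Stain):
            if ev.dye not in stained:
                stained.append(ev.dye)
        else:
            if ev.region not in uncaged:
                uncaged[ev.region] = set()
                order.append(ev.region)
            for dye in stained:
                if ev.exposure_seconds >= protocol.dyes[dye]:
                    uncaged[ev.region].add(dye)
    codes = [RegionCode(region, frozenset(uncaged[region])) for region in order]
    n_distinct = len({c.code for c in codes if c.code})
    return codes, n_distinct


def achievable_codes(thresholds, stain_order=None) -> set:
    """Codes reachable by regions sharing one staining sequence.

    ``thresholds`` maps dye name -> uncaging threshold. All regions of an
    experiment see the same stain order; each region independently chooses
    its exposure in every gap between stains (0 or one of the thresholds —
    intermediate exposures add nothing under the hard-threshold model).
    With ``stain_order=None`` the order maximizing the count of distinct
    non-empty codes is used. Exponential; intended for small dye sets and
    as the reference for :func:`max_codes`.
    """
    if stain_order is not None:
        orders = [tuple(stain_order)]
    else:
        orders = list(permutations(thresholds))
    levels = sorted({0.0} | {float(t) for t in thresholds.values()})
    best: set = set()
    for order in orders:
        codes: set = set()
        # m[i] = max exposure applied after stain i (before stain i+1 / end)
        for m in product(levels, repeat=len(order)):
            suffix_max = 0.0
            code = set()
            for i in range(len(order) - 1, -1, -1):
                suffix_max = max(suffix_max, m[i])
                if suffix_max >= thresholds[order[i]]:
                    code.add(order[i])
            if code:
                codes.add(frozenset(code))
        if len(codes) > len(best):
            best = codes
    return best


def max_codes(n_dyes: int, n_threshold_classes: int) -> int:
    """Maximum number of distinct non-empty codes for a dye budget.

    ``n_dyes`` dyes are split across ``n_threshold_classes`` distinct
    uncaging thresholds; within a class only "prefix" states are reachable
    (a later activation re-uncages every stained dye of the class), so a
    class of size n contributes n + 1 states and classes multiply. The
    split maximizing ``prod (n_k + 1) - 1`` is the balanced one.
    """
    if n_dyes < 1 or n_threshold_classes < 1:
        raise ValueError("n_dyes and n_threshold_classes must be >= 1")
    n_classes = min(n_dyes, n_threshold_classes)
    base, extra = divmod(n_dyes, n_classes)
    total = 1
    for k in range(n_classes):
        total *= base + (1 if k < extra else 0) + 1
    return total - 1


@dataclass
class ExposurePolicy:
    """Phototoxicity-limited exposure budget at a reference magnification.

    The photon flux through an objective scales with the inverse square of
    the field-of-view side length, i.e. with magnification squared, so the
    safe exposure scales with (reference_magnification / magnification)^2.
    """

    reference_limit_seconds: float = 4.0
    reference_magnification: float = 40.0

    def __post_init__(self):
        if self.reference_limit_seconds <= 0 or self.reference_magnification <= 0:
            raise ValueError("exposure policy values must be positive")


def exposure_limit(magnification: float,
                   policy: ExposurePolicy | None = None) -> float:
    """Upper photoactivation exposure (seconds) at a given magnification."""
    if magnification <= 0:
        raise ValueError("magnification must be positive")
    policy = policy or ExposurePolicy()
    return policy.reference_limit_seconds * (
        policy.reference_magnification / magnification
    ) ** 2


@dataclass
class YieldAccount:
    """Photoactivated-cell recovery bookkeeping."""

    n_regions: int
    cells_per_region: int
    n_recovered: int

    def __post_init__(self):
        if self.n_recovered < 0:
            raise ValueError("n_recovered must be non-negative")
        if self.n_regions * self.cells_per_region <= 0:
            raise ValueError("n_regions * cells_per_region must be positive")


def expected_yield(acct: YieldAccount) -> float:
    """Recovered cells as a fraction of expected photoactivated cells."""
    return acct.n_recovered / (acct.n_regions * acct.cells_per_region)


def five_color_protocol() -> DyeProtocol:
    """Three-dye sequential protocol encoding five distinct regions.

    Calcein NVOC uncages after 10 s of near-UV; PA-JF549 and PA-JF646 after
    0.5 s. Staining them in that order and activating regions between
    staining rounds yields the five codes {calcein}, {JF549},
    {calcein, JF549}, {JF549, JF646} and all three.
    """
    C, J549, J646 = "calcein_nvoc", "PA-JF549", "PA-JF646"
    return DyeProtocol(
        dyes={C: 10.0, J549: 0.5, J646: 0.5},
        events=[
            Stain(C),
            Activate("R1", 10.0),   # calcein alone
            Activate("R3", 10.0),
            Activate("R5", 10.0),
            Stain(J549),
            Activate("R2", 0.5),    # JF549 alone
            Activate("R3", 0.5),    # calcein + JF549
            Activate("R4", 0.5),
            Stain(J646),
            Activate("R4", 0.5),    # JF549 + JF646
            Activate("R5", 0.5),    # all three
        ],
    )
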