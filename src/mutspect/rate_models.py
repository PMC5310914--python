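"""Closed-form arithmetic linking signature proportions to rate changes.

If a sample carries M mutations of which N belong to a signature
(p = N/M), and only that signature's count increases by dN while all other
mutation counts stay fixed, the new proportion is q = (N+dN)/(M+dN) and the
relative increase in the *total* mutation rate is

    dN/M = (q - p) / (1 - q).

Also here: the repeat-mutation share implied by excess cross-population
sharing, and the conversion of coalescent time units to years.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["RateChange", "rate_increase", "repeat_share", "coalescent_to_years"]


@dataclass(frozen=True)
class RateChange:
    """A baseline and new signature proportion with the implied relative
    increase in total mutation rate."""

    p: float
    q: float

    def __post_init__(self) -> None:
        if not 0 <= self.p < 1:
            raise ValueError("p must lie in [0, 1)")
        if not 0 <= self.q < 1:
            raise ValueError("q must lie in [0, 1)")

    @property
    def delta(self) -> float:
        return (self.q - self.p) / (1 - self.q)

    @property
    def delta_percent(self) -> float:
        return 100.0 * self.delta


def rate_increase(p: float, q: float) -> float:
    """Relative increase in total mutation rate, (q - p)/(1 - q)."""
    return RateChange(p, q).delta


def repeat_share(share_sig: float, share_all: float, method: str = "excess") -> float:
    """Estimated fraction of signature variants that are repeat mutations,
    from the cross-split sharing proportion of signature variants versus all
    variants.

    ``excess`` (default) returns share_sig - share_all. ``solve`` models
    repeat doubletons as always cross-split and returns
    (share_sig - share_all)/(1 - share_all).
    """
    if not 0 <= share_all <= share_sig <= 1:
        raise ValueError("need 0 <= share_all <= share_sig <= 1")
    if method == "excess":
        return share_sig - share_all
    if method == "solve":
        if share_all == 1:
            raise ValueError("share_all = 1: solve method undefined")
        return (share_sig - share_all) / (1 - share_all)
    raise ValueError(f"unknown method {method!r}")


def coalescent_to_years(s: float, ne: float, generation_years: float) -> float:
    """Convert ``s`` coalescent units to years: s x 2 Ne x generation time
    (diploid scaling: one coalescent unit is 2 Ne generations)."""
    if s < 0 or ne <= 0 or generation_years <= 0:
        raise ValueError("s must be >= 0 and Ne, generation time positive")
    return s * 2.0 * ne * generation_years
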