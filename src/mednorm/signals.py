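"""Report-based disproportionality analysis.

Implements the two standard pharmacovigilance screening statistics over
a spontaneous-report table, with a report-based unit of analysis: each
report contributes at most once to any drug-event cell, regardless of
how many times it mentions the drug or the event.

Information Component (IC), in bits:

    E     = (a + b)(a + c) / n
    IC    = log2((a + 0.5) / (E + 0.5))
    IC025 = IC - 3.3 (a + 0.5)^-1/2 - 2   (a + 0.5)^-3/2
    IC975 = IC + 2.4 (a + 0.5)^-1/2 + 0.5 (a + 0.5)^-3/2

where a is the observed drug-and-event report count and E its
expectation under independence; the credibility bounds use the
closed-form approximation of the IC posterior common in the
disproportionality literature (Noren-style coefficients).  The +0.5
shrinkage pulls small-count ICs toward zero.

Reporting Odds Ratio (ROR):

    ROR = ad / bc,   CI95 = exp(ln ROR +/- 1.96 sqrt(1/a+1/b+1/c+1/d))

with the Haldane-Anscombe +0.5 continuity correction applied to every
cell whenever any cell is zero.

A signal of disproportionate reporting (SDR) is flagged when the lower
bound of the 95% interval clears its null value: IC025 > 0 or ROR lower
bound > 1.  ``compare_aggregation`` contrasts per-variant statistics
with statistics after name aggregation, the mechanism by which
standardization recovers signals diluted across name variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ReportRecord",
    "ContingencyTable",
    "SignalStats",
    "contingency",
    "information_component",
    "reporting_odds_ratio",
    "signal_stats",
    "compare_aggregation",
]

_Z95 = 1.96


@dataclass(frozen=True)
class ReportRecord:
    """One spontaneous report: its drugs and its event terms, as sets."""

    report_id: str
    drugs: frozenset[str] = frozenset()
    events: frozenset[str] = frozenset()


@dataclass(frozen=True)
class ContingencyTable:
    """Report-level 2x2 counts for one drug-event pair."""

    a: int  # drug & event
    b: int  # drug, no event
    c: int  # event, no drug
    d: int  # neither

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def drug_margin(self) -> int:
        return self.a + self.b

    @property
    def event_margin(self) -> int:
        return self.a + self.c

    @property
    def expected(self) -> float:
        """Expected drug-and-event count under independence."""
        if self.n_total == 0:
            raise ValueError("empty table has no expectation")
        return self.drug_margin * self.event_margin / self.n_total


@dataclass(frozen=True)
class SignalStats:
    ic: float
    ic025: float
    ic975: float
    ror: float
    ror_low: float
    ror_high: float
    n: int  # observed co-report count (cell a)
    ror_corrected: bool = False

    @property
    def sdr_ic(self) -> bool:
        return self.ic025 > 0.0

    @property
    def sdr_ror(self) -> bool:
        return self.ror_low > 1.0

    @property
    def sdr(self) -> bool:
        return self.sdr_ic or self.sdr_ror


def contingency(
    reports: list[ReportRecord], drug_key: str, event_key: str
) -> ContingencyTable:
    """Report-level 2x2 table for one drug-event pair.

    A drug or event absent from every report is not an error; it simply
    yields a table with a = 0.
    """
    if not reports:
        raise ValueError("reports must be non-empty")
    a = b = c = d = 0
    for rep in reports:
        has_drug = drug_key in rep.drugs
        has_event = event_key in rep.events
        if has_drug and has_event:
            a += 1
        elif has_drug:
            b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def information_component(t: ContingencyTable) -> tuple[float, float, float]:
    """(IC, IC025, IC975) in bits for one 2x2 table."""
    if t.n_total == 0:
        raise ValueError("information component undefined for empty table")
    e = t.expected
    a_shr = t.a + 0.5
    ic = math.log2(a_shr / (e + 0.5))
    ic025 = ic - 3.3 * a_shr ** -0.5 - 2.0 * a_shr ** -1.5
    ic975 = ic + 2.4 * a_shr ** -0.5 + 0.5 * a_shr ** -1.5
    return ic, ic025, ic975


def reporting_odds_ratio(
    t: ContingencyTable,
) -> tuple[float, float, float, bool]:
    """(ROR, low, high, corrected) with 95% CI.

    The Haldane-Anscombe correction (+0.5 to every cell) is applied,
    and flagged, whenever any cell is zero.  Raises ``ValueError`` when
    two or more margins are empty (the odds ratio is then meaningless
    even with correction).
    """
    if t.n_total == 0:
        raise ValueError("reporting odds ratio undefined for empty table")
    margins = [t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d]
    if sum(m == 0 for m in margins) >= 2:
        raise ValueError("two or more empty margins: ROR undefined")
    corrected = 0 in (t.a, t.b, t.c, t.d)
    shift = 0.5 if corrected else 0.0
    a, b, c, d = (t.a + shift, t.b + shift, t.c + shift, t.d + shift)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    low = math.exp(math.log(ror) - _Z95 * se)
    high = math.exp(math.log(ror) + _Z95 * se)
    return ror, low, high, corrected


def signal_stats(t: ContingencyTable) -> SignalStats:
    """All disproportionality statistics for one table."""
    ic, ic025, ic975 = information_component(t)
    ror, low, high, corrected = reporting_odds_ratio(t)
    return SignalStats(
        ic=ic, ic025=ic025, ic975=ic975,
        ror=ror, ror_low=low, ror_high=high,
        n=t.a, ror_corrected=corrected,
    )


@dataclass(frozen=True)
class AggregationComparison:
    per_variant: dict[str, SignalStats]
    aggregated: dict[str, SignalStats]  # canonical drug key -> stats
    per_variant_tables: dict[str, ContingencyTable] = field(repr=False, default_factory=dict)
    aggregated_tables: dict[str, ContingencyTable] = field(repr=False, default_factory=dict)


def compare_aggregation(
    reports: list[ReportRecord],
    variant_map: dict[str, str],
    event_key: str,
) -> AggregationComparison:
    """Fragmented-versus-aggregated signal statistics for one event.

    Per-variant statistics are computed on the raw drug keys of
    *variant_map*; aggregated statistics are computed after every
    variant key is replaced by its canonical key.  The comparison
    exposes the signal-dilution effect of name fragmentation: the same
    reports can show no per-variant SDR yet a clear aggregated one.
    """
    per_variant: dict[str, SignalStats] = {}
    pv_tables: dict[str, ContingencyTable] = {}
    for variant in sorted(variant_map):
        table = contingency(reports, variant, event_key)
        pv_tables[variant] = table
        per_variant[variant] = signal_stats(table)

    remapped = [
        ReportRecord(
            report_id=rep.report_id,
            drugs=frozenset(variant_map.get(drg, drg) for drg in rep.drugs),
            events=rep.events,
        )
        for rep in reports
    ]
    aggregated: dict[str, SignalStats] = {}
    agg_tables: dict[str, ContingencyTable] = {}
    for canonical in sorted(set(variant_map.values())):
        table = contingency(remapped, canonical, event_key)
        agg_tables[canonical] = table
        aggregated[canonical] = signal_stats(table)

    return AggregationComparison(
        per_variant=per_variant,
        aggregated=aggregated,
        per_variant_tables=pv_tables,
        aggregated_tables=agg_tables,
    )
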