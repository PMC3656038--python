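"""Published regional SOC accounting for the Australian wheat belt, 1960-2010.

These are the published decadal estimates (areas, densities, carbon inputs
and stock changes with 95% confidence intervals) for the five wheat-growing
state regions and the belt as a whole.  They serve as the worked-example
input for the aggregation and rate arithmetic: rebuilding the belt row from
the regional rows exercises :func:`soilcarbon.regional.aggregate_belt`, and
the decadal loss rates and period shares follow from
:func:`soilcarbon.regional.loss_rates_and_shares`.

Values are as printed: densities in Mg C ha⁻¹, inputs in Mg C ha⁻¹ yr⁻¹,
stock changes in Tg C, areas in Mha.
"""

from __future__ import annotations

from .regional import DecadeRecord, RegionalSummary

DECADE_LABELS = ("1960s", "1970s", "1980s", "1990s", "2000s")

# region -> (area, initial (v, lo, hi),
#            [(density (v, lo, hi), c_input, change (v, lo, hi)), ...])
_PUBLISHED = {
    "QLD": (
        0.86,
        (33, 22, 43),
        [
            ((30, 21, 39), 1.18, (-4, -6, -2)),
            ((26, 19, 33), 1.13, (-3, -4, -1)),
            ((23, 17, 29), 1.27, (-2, -3, -1)),
            ((21, 16, 26), 1.14, (-2, -3, -1)),
            ((20, 15, 23), 1.29, (-1, -2, -1)),
        ],
    ),
    "NSW": (
        3.83,
        (31, 21, 42),
        [
            ((28, 19, 38), 0.88, (-19, -28, -9)),
            ((25, 17, 32), 0.93, (-11, -17, -6)),
            ((22, 16, 28), 0.99, (-7, -12, -3)),
            ((21, 16, 26), 1.31, (-5, -8, -1)),
            ((20, 16, 24), 1.02, (-6, -9, -3)),
        ],
    ),
    "WA": (
        5.28,
        (29, 24, 34),
        [
            ((26, 22, 30), 0.86, (-23, -30, -17)),
            ((23, 20, 26), 0.96, (-13, -17, -9)),
            ((21, 18, 24), 1.03, (-10, -13, -6)),
            ((20, 17, 22), 1.48, (-3, -6, 0)),
            ((19, 17, 21), 1.40, (-4, -5, -2)),
        ],
    ),
    "SA": (
        2.87,
        (29, 23, 34),
        [
            ((26, 21, 31), 0.98, (-11, -14, -6)),
            ((24, 20, 28), 1.01, (-6, -9, -4)),
            ((22, 18, 25), 1.10, (-4, -6, -3)),
            ((21, 18, 24), 1.43, (-2, -3, 0)),
            ((21, 18, 23), 1.35, (-3, -4, -1)),
        ],
    ),
    "VIC": (
        2.24,
        (28, 24, 33),
        [
            ((26, 22, 30), 1.15, (-7, -9, -5)),
            ((24, 21, 27), 1.31, (-4, -5, -2)),
            ((23, 21, 25), 1.41, (-2, -4, -1)),
            ((22, 20, 24), 1.40, (-2, -2, -1)),
            ((21, 20, 23), 1.34, (-2, -3, -1)),
        ],
    ),
}

# Belt row as printed (used to cross-check the aggregation, not derived).
_PUBLISHED_BELT = (
    15.08,
    (30, 23, 36),
    [
        ((27, 21, 33), 0.95, (-64, -87, -39)),
        ((24, 19, 28), 1.02, (-37, -52, -22)),
        ((22, 18, 26), 1.10, (-25, -38, -14)),
        ((21, 17, 24), 1.40, (-14, -22, -3)),
        ((20, 17, 23), 1.28, (-16, -23, -8)),
    ],
)

REGION_NAMES = tuple(_PUBLISHED)
REGION_AREAS_MHA = {name: rec[0] for name, rec in _PUBLISHED.items()}


def _build(name: str, rec) -> RegionalSummary:
    area, (init, init_lo, init_hi), decades = rec
    return RegionalSummary(
        name=name,
        area_mha=area,
        initial_density=float(init),
        initial_ci=(float(init_lo), float(init_hi)),
        decades=tuple(
            DecadeRecord(
                label=DECADE_LABELS[i],
                density=float(dv),
                c_input=float(cin),
                change_tg=float(cv),
                density_ci=(float(dlo), float(dhi)),
                change_ci=(float(clo), float(chi)),
            )
            for i, ((dv, dlo, dhi), cin, (cv, clo, chi)) in enumerate(decades)
        ),
    )


def published_region_summaries() -> list[RegionalSummary]:
    """The five published regional summaries (QLD, NSW, WA, SA, VIC)."""
    return [_build(name, rec) for name, rec in _PUBLISHED.items()]


def published_belt_summary() -> RegionalSummary:
    """The published belt-level summary row (as printed, not re-derived)."""
    return _build("Wheat belt", _PUBLISHED_BELT)
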