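"""Unit conversions used at the package I/O boundary.

Internal convention: fluxes and uptake/excretion rates are expressed in
nmol/min/ug protein, metabolite pools in nmol/ug protein, medium
concentrations in mM, times in hours at I/O (converted to minutes
internally where rates are involved).
"""

MINUTES_PER_HOUR = 60.0

#: Molar masses (g/mol) of medium nutrients measured by the bioanalyzer.
MOLAR_MASS = {
    "glucose": 180.156,
    "glutamine": 146.145,
    "lactate": 90.078,
    "glutamate": 147.130,
}


def g_per_l_to_mM(value_g_per_l: float, compound: str) -> float:
    """Convert a mass concentration (g/l) to millimolar.

    >>> round(g_per_l_to_mM(0.584, "glutamine"), 2)
    4.0
    """
    try:
        mw = MOLAR_MASS[compound]
    except KeyError:
        raise KeyError(f"no molar mass on record for {compound!r}") from None
    return value_g_per_l / mw * 1000.0


def mM_to_g_per_l(value_mM: float, compound: str) -> float:
    return value_mM * MOLAR_MASS[compound] / 1000.0


def hours_to_minutes(t_h: float) -> float:
    return t_h * MINUTES_PER_HOUR


def minutes_to_hours(t_min: float) -> float:
    return t_min / MINUTES_PER_HOUR
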