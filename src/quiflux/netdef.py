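"""Programmatic definition of the central-carbon network.

The packaged JSON resource ``resources/central_carbon_network.json`` is the
serialized form of :func:`default_config`; a unit test keeps the two in sync.

Model summary
-------------
A flux-balanced model of glycolysis, the pentose phosphate pathway (PPP),
a truncatable TCA cycle and glutamine entry, at the coarse granularity of
"number of 13C atoms per metabolite".  Free fluxes (nmol/min/ug protein):

========  ==========================================================
F0        hexose-P -> pentose-P (oxidative PPP, releases CO2)
F1        hexose-P -> FBP (phosphofructokinase)
F2        DHAP/GAP -> 3-phosphoglycerate (lower glycolysis)
F3        fatty-acid breakdown -> acetyl-CoA
F4        non-oxidative PPP return, in pentose-P consumption units
          (3 pentose-P -> 2 hexose-P + 1 triose-P, via S7P)
F5        pyruvate -> acetyl-CoA (pyruvate dehydrogenase, releases CO2)
F7        citrate -> alpha-ketoglutarate (forward TCA, releases CO2)
F8        alpha-ketoglutarate -> succinate (releases CO2)
F10       citrate -> acetyl-CoA + OAA (ATP-citrate lyase; the OAA
          returns through the malate pool)
F11       alpha-ketoglutarate + CO2 -> citrate (reductive carboxylation)
F12       FBP <-> 2 triose-P exchange (labeling only, no net flux)
========  ==========================================================

F9 is not a flux but the latent (never-labeling) hexose-phosphate pool
size.  A latent citrate fraction plays the same role for citrate.

Measured exchange rates: A glucose uptake, B lactate excretion, C glutamine
uptake, D glutamate excretion.  Dependent parameters, fixed by steady-state
balance of the pyruvate, glutamate and oxaloacetate nodes:

    Y = F2 - B - F5              (anaplerosis, pyruvate -> OAA)
    X = C - D - F8 - F11 + F7    (protein synthesis drain on glutamate)
    Z = F7 + F10 - F11 - Y       (net malate -> OAA)

Remaining branch nodes are closed by non-negative biosynthetic drain
fluxes (nucleotide synthesis, glycerol-3-P, hexose-P biosynthesis,
fatty-acid synthesis, malate-derived amino acids) whose expressions are
also derived from balance.
"""

from __future__ import annotations

import copy
from typing import Any

THIRD = 1.0 / 3.0

# ---------------------------------------------------------------------------
# metabolites

_METABOLITES = [
    # name, carbons, notes
    ("hexp", 6, {"latent": "pool"}),       # G1P+G6P+F6P; latent sub-pool = F9
    ("fbp", 6, {}),
    ("dhap", 3, {}),                        # DHAP+GAP triose pool
    ("pg3", 3, {}),
    ("pep", 3, {}),
    ("pyr", 3, {}),
    ("lac", 3, {}),
    ("penp", 5, {}),                        # R5P+Ru5P+X5P
    ("s7p", 7, {}),
    ("accoa", 2, {"unmeasured": True}),     # acetyl unit
    ("fa", 2, {"unmeasured": True, "reservoir": True}),  # fatty-acyl 2C units
    ("cit", 6, {"latent": "fraction"}),
    ("akg", 5, {}),
    ("suc", 4, {}),
    ("mal", 4, {}),                         # malate (+measured proxy for OAA)
    ("oaa", 4, {"virtual": True}),          # zero-pool mixing node
    ("glu", 5, {}),
]

_EXTERNALS = {"glc_medium": 6, "gln_medium": 5}

# ---------------------------------------------------------------------------
# fluxes

_FREE_FLUXES = ["F0", "F1", "F2", "F3", "F4", "F5", "F7", "F8", "F10", "F11", "F12"]
_RATES = ["A", "B", "C", "D"]

# linear expressions {symbol: coefficient} over free fluxes, rates and the
# dependent symbols X/Y/Z; each derived flux is attributed to the node whose
# balance defines it (used for infeasibility reporting).
_DEPENDENT = {
    "Y": {"expr": {"F2": 1, "B": -1, "F5": -1}, "node": "pyr"},
    "X": {"expr": {"C": 1, "D": -1, "F8": -1, "F11": -1, "F7": 1}, "node": "glu"},
    "Z": {"expr": {"F7": 1, "F10": 1, "F11": -1, "F2": -1, "B": 1, "F5": 1}, "node": "oaa"},
}

_DERIVED = {
    "F6": {"expr": {"F7": 1, "F10": 1, "F11": -1}, "node": "cit"},
    "ntp_drain": {"expr": {"F0": 1, "F4": -1}, "node": "penp"},
    "hexp_drain": {"expr": {"A": 1, "F4": 2 * THIRD, "F0": -1, "F1": -1}, "node": "hexp"},
    "g3p_drain": {"expr": {"F1": 2, "F4": THIRD, "F2": -1}, "node": "dhap"},
    # fa_syn = F5 + F3 + F10 - F6 with F6 = F7 + F10 - F11 (F10 cancels)
    "fa_syn": {"expr": {"F5": 1, "F3": 1, "F11": 1, "F7": -1}, "node": "accoa"},
    "glu_akg": {"expr": {"F8": 1, "F11": 1, "F7": -1}, "node": "akg"},
    "mal_drain": {"expr": {"F8": 1, "F10": 1, "Z": -1}, "node": "mal"},
}

_REACTIONS = [
    # id, flux expression ({sym: coeff}), substrates, products
    ("glc_uptake", {"A": 1}, {"glc_medium": 1}, {"hexp": 1}),
    ("F0", {"F0": 1}, {"hexp": 1}, {"penp": 1}),
    ("F1", {"F1": 1}, {"hexp": 1}, {"fbp": 1}),
    ("aldolase", {"F1": 1}, {"fbp": 1}, {"dhap": 2}),
    ("F12_fwd", {"F12": 1}, {"fbp": 1}, {"dhap": 2}),
    ("F12_rev", {"F12": 1}, {"dhap": 2}, {"fbp": 1}),
    ("F2", {"F2": 1}, {"dhap": 1}, {"pg3": 1}),
    ("enolase", {"F2": 1}, {"pg3": 1}, {"pep": 1}),
    ("pyr_kinase", {"F2": 1}, {"pep": 1}, {"pyr": 1}),
    ("ldh", {"B": 1}, {"pyr": 1}, {"lac": 1}),
    ("lac_excretion", {"B": 1}, {"lac": 1}, {}),
    ("ntp_drain", {"ntp_drain": 1}, {"penp": 1}, {}),
    ("tk1", {"F4": THIRD}, {"penp": 2}, {"s7p": 1, "dhap": 1}),
    ("ta_tk2", {"F4": THIRD}, {"s7p": 1, "penp": 1}, {"hexp": 2}),
    ("hexp_drain", {"hexp_drain": 1}, {"hexp": 1}, {}),
    ("g3p_drain", {"g3p_drain": 1}, {"dhap": 1}, {}),
    ("F5", {"F5": 1}, {"pyr": 1}, {"accoa": 1}),
    ("Y", {"Y": 1}, {"pyr": 1}, {"oaa": 1}),
    ("F6", {"F6": 1}, {"accoa": 1, "oaa": 1}, {"cit": 1}),
    ("F7", {"F7": 1}, {"cit": 1}, {"akg": 1}),
    ("F8", {"F8": 1}, {"akg": 1}, {"suc": 1}),
    ("sdh_fum", {"F8": 1}, {"suc": 1}, {"mal": 1}),
    ("Z", {"Z": 1}, {"mal": 1}, {"oaa": 1}),
    ("mal_drain", {"mal_drain": 1}, {"mal": 1}, {}),
    ("F10", {"F10": 1}, {"cit": 1}, {"accoa": 1, "mal": 1}),
    ("F3", {"F3": 1}, {"fa": 1}, {"accoa": 1}),
    ("fa_syn", {"fa_syn": 1}, {"accoa": 1}, {"fa": 1}),
    ("gln_uptake", {"C": 1}, {"gln_medium": 1}, {"glu": 1}),
    ("glu_excretion", {"D": 1}, {"glu": 1}, {}),
    ("X", {"X": 1}, {"glu": 1}, {}),
    ("glu_akg", {"glu_akg": 1}, {"glu": 1}, {"akg": 1}),
    ("F11", {"F11": 1}, {"akg": 1}, {"cit": 1}),
]


# ---------------------------------------------------------------------------
# label channel helpers

def _ch(reaction: str, inputs, outputs, labeled_loss: int = 0,
        unlabeled_loss: int = 0, unlabeled_gain: int = 0,
        label_writedown: int = 0) -> dict:
    """One labeling channel.

    ``labeled_loss``/``unlabeled_loss`` are carbons physically leaving as
    CO2; ``unlabeled_gain`` is CO2 fixation; ``label_writedown`` counts 13C
    atoms deliberately recorded as unlabeled because the true product form
    is a declared low-abundance exclusion.
    """
    return {
        "reaction": reaction,
        "inputs": [list(i) for i in inputs],
        "outputs": [list(o) for o in outputs],
        "labeled_loss": labeled_loss,
        "unlabeled_loss": unlabeled_loss,
        "unlabeled_gain": unlabeled_gain,
        "label_writedown": label_writedown,
    }


def _map_channels(reaction: str, met: str, carbons: int, mapping: dict) -> list[dict]:
    """Unimolecular per-form channels.

    ``mapping``: form -> (outputs, labeled_loss, unlabeled_loss,
    unlabeled_gain[, label_writedown]); outputs is a list of
    (met, form, count).
    """
    out = []
    for n, spec in sorted(mapping.items()):
        outputs, llo, ulo, uga = spec[:4]
        wd = spec[4] if len(spec) > 4 else 0
        out.append(_ch(reaction, [(met, n)], outputs, llo, ulo, uga, wd))
    return out


def _drain_channels(reaction: str, met: str, carbons: int, forms) -> list[dict]:
    return [
        _ch(reaction, [(met, n)], [], labeled_loss=n, unlabeled_loss=carbons - n)
        for n in sorted(forms)
    ]


def _carry(reaction: str, met_in: str, met_out: str, forms,
           extra_loss_c: int = 0) -> list[dict]:
    """Same-label carry-over channels (no carbon change unless stated)."""
    chans = []
    for n in sorted(forms):
        chans.append(_ch(reaction, [(met_in, n)], [(met_out, n, 1)],
                         labeled_loss=0, unlabeled_loss=extra_loss_c))
    return chans


# ---------------------------------------------------------------------------
# tracer models

def _glucose_tracer() -> dict:
    """Labeled-form model for the [U-13C]-glucose switch (36 states)."""
    states = {
        "hexp": [0, 6], "fbp": [0, 6], "dhap": [0, 3], "pg3": [0, 3],
        "pep": [0, 3], "pyr": [0, 3], "lac": [0, 3], "penp": [0, 5],
        "s7p": [0, 7], "accoa": [0, 2], "fa": [0, 2],
        "cit": [0, 2, 3, 4, 5], "akg": [0, 2, 3], "suc": [0, 2, 3],
        "mal": [0, 2, 3],
    }
    ch: list[dict] = []
    ch.append(_ch("glc_uptake", [("glc_medium", 6)], [("hexp", 6, 1)]))
    ch += _map_channels("F0", "hexp", 6, {
        0: ([("penp", 0, 1)], 0, 1, 0),
        6: ([("penp", 5, 1)], 1, 0, 0),          # CO2 from labeled C1
    })
    ch += _carry("F1", "hexp", "fbp", [0, 6])
    ch += _map_channels("aldolase", "fbp", 6, {
        0: ([("dhap", 0, 2)], 0, 0, 0),
        6: ([("dhap", 3, 2)], 0, 0, 0),
    })
    ch += _map_channels("F12_fwd", "fbp", 6, {
        0: ([("dhap", 0, 2)], 0, 0, 0),
        6: ([("dhap", 3, 2)], 0, 0, 0),
    })
    # reverse exchange: triose pairs treated as co-labeled (cohort rule);
    # mixed pairs are a declared model exclusion.
    ch.append(_ch("F12_rev", [("dhap", 0)], [("fbp", 0, 1)]))
    ch.append(_ch("F12_rev", [("dhap", 3)], [("fbp", 6, 1)]))
    for met_in, met_out, rxn in [("dhap", "pg3", "F2"), ("pg3", "pep", "enolase"),
                                 ("pep", "pyr", "pyr_kinase"), ("pyr", "lac", "ldh")]:
        ch += _carry(rxn, met_in, met_out, [0, 3])
    ch += _drain_channels("lac_excretion", "lac", 3, [0, 3])
    ch += _drain_channels("ntp_drain", "penp", 5, [0, 5])
    # TK1, pentose pairs co-labeled (cohort): 2 P5P -> S7P + GAP
    ch.append(_ch("tk1", [("penp", 0)], [("s7p", 0, 1), ("dhap", 0, 1)]))
    ch.append(_ch("tk1", [("penp", 5)], [("s7p", 7, 1), ("dhap", 3, 1)]))
    # TA+TK2 lump: S7P + P5P -> 2 hexose-P (bilinear; mismatched channels
    # project onto tracked forms with declared label loss)
    ch.append(_ch("ta_tk2", [("s7p", 0), ("penp", 0)], [("hexp", 0, 2)]))
    ch.append(_ch("ta_tk2", [("s7p", 7), ("penp", 5)], [("hexp", 6, 2)]))
    ch.append(_ch("ta_tk2", [("s7p", 7), ("penp", 0)],
                  [("hexp", 6, 1), ("hexp", 0, 1)], label_writedown=1))
    ch.append(_ch("ta_tk2", [("s7p", 0), ("penp", 5)],
                  [("hexp", 0, 2)], label_writedown=5))
    ch += _drain_channels("hexp_drain", "hexp", 6, [0, 6])
    ch += _drain_channels("g3p_drain", "dhap", 3, [0, 3])
    ch += _map_channels("F5", "pyr", 3, {
        0: ([("accoa", 0, 1)], 0, 1, 0),
        3: ([("accoa", 2, 1)], 1, 0, 0),         # PDH CO2 carries a label
    })
    # citrate synthase: acetyl (2C) x OAA (4C) -> citrate (6C), bilinear
    for na in (0, 2):
        for no in (0, 2, 3):
            ch.append(_ch("F6", [("accoa", na), ("oaa", no)],
                          [("cit", na + no, 1)]))
    ch += _map_channels("F7", "cit", 6, {
        0: ([("akg", 0, 1)], 0, 1, 0),
        2: ([("akg", 2, 1)], 0, 1, 0),           # acetyl carbons retained
        3: ([("akg", 3, 1)], 0, 1, 0),
        4: ([("akg", 3, 1)], 1, 0, 0),
        5: ([("akg", 3, 1)], 1, 0, 0, 1),        # 4x-aKG excluded (declared)
    })
    # glutamine-derived (unlabeled under this tracer) influx into aKG
    ch.append(_ch("glu_akg", [("glu", 0)], [("akg", 0, 1)]))
    ch += _map_channels("F8", "akg", 5, {
        0: ([("suc", 0, 1)], 0, 1, 0),
        2: ([("suc", 2, 1)], 0, 1, 0),
        3: ([("suc", 3, 1)], 0, 1, 0),
    })
    ch += _carry("sdh_fum", "suc", "mal", [0, 2, 3], extra_loss_c=0)
    ch += _drain_channels("mal_drain", "mal", 4, [0, 2, 3])
    # ATP-citrate lyase: citrate -> acetyl + OAA(-> malate pool)
    ch += _map_channels("F10", "cit", 6, {
        0: ([("accoa", 0, 1), ("mal", 0, 1)], 0, 0, 0),
        2: ([("accoa", 2, 1), ("mal", 0, 1)], 0, 0, 0),
        3: ([("accoa", 0, 1), ("mal", 3, 1)], 0, 0, 0),
        4: ([("accoa", 2, 1), ("mal", 2, 1)], 0, 0, 0),
        5: ([("accoa", 2, 1), ("mal", 3, 1)], 0, 0, 0),
    })
    ch += _carry("F3", "fa", "accoa", [0, 2])
    ch += _carry("fa_syn", "accoa", "fa", [0, 2])
    # reductive carboxylation fixes an unlabeled CO2
    ch += _map_channels("F11", "akg", 5, {
        0: ([("cit", 0, 1)], 0, 0, 1),
        2: ([("cit", 2, 1)], 0, 0, 1),
        3: ([("cit", 3, 1)], 0, 0, 1),
    })
    # pyruvate carboxylase and malate dehydrogenase feed the OAA mixing node
    mixer = [
        {"flux": "Y", "source": "pyr", "map": {"0": 0, "3": 3}, "unlabeled_gain": 1},
        {"flux": "Z", "source": "mal", "map": {"0": 0, "2": 2, "3": 3},
         "unlabeled_gain": 0},
    ]
    return {"entry": "glc_medium",
            "external_dists": {"glc_medium": {"6": 1.0}, "gln_medium": {"0": 1.0}},
            "states": states, "channels": ch, "mixers": {"oaa": mixer}}


def _glutamine_tracer() -> dict:
    """Labeled-form model for the [U-13C]-glutamine switch (19 states).

    Glycolytic and PPP metabolites never label from glutamine in this
    network (no PEPCK / malic enzyme), so they are omitted; reactions that
    consume them draw implicitly unlabeled substrate.
    """
    states = {
        "glu": [0, 5], "akg": [0, 3, 5], "suc": [0, 3, 4],
        "mal": [0, 3, 4], "cit": [0, 3, 4, 5], "accoa": [0, 2], "fa": [0, 2],
    }
    ch: list[dict] = []
    ch.append(_ch("gln_uptake", [("gln_medium", 5)], [("glu", 5, 1)]))
    ch += _drain_channels("glu_excretion", "glu", 5, [0, 5])
    ch += _drain_channels("X", "glu", 5, [0, 5])
    ch += _carry("glu_akg", "glu", "akg", [0, 5])
    ch += _map_channels("F8", "akg", 5, {
        0: ([("suc", 0, 1)], 0, 1, 0),
        3: ([("suc", 3, 1)], 0, 1, 0),
        5: ([("suc", 4, 1)], 1, 0, 0),           # CO2 carries a label
    })
    ch += _carry("sdh_fum", "suc", "mal", [0, 3, 4])
    ch += _drain_channels("mal_drain", "mal", 4, [0, 3, 4])
    # unlabeled glucose-derived acetyl
    ch.append(_ch("F5", [("pyr", 0)], [("accoa", 0, 1)], unlabeled_loss=1))
    for na in (0, 2):
        for no in (0, 3, 4):
            ncit = na + no
            if ncit == 2:
                # 2x-citrate from relabeled acetyl excluded (declared)
                ch.append(_ch("F6", [("accoa", na), ("oaa", no)],
                              [("cit", 0, 1)], label_writedown=2))
            elif ncit == 6:
                # 6x-citrate excluded (declared)
                ch.append(_ch("F6", [("accoa", na), ("oaa", no)],
                              [("cit", 5, 1)], label_writedown=1))
            else:
                ch.append(_ch("F6", [("accoa", na), ("oaa", no)],
                              [("cit", ncit, 1)]))
    ch += _map_channels("F7", "cit", 6, {
        0: ([("akg", 0, 1)], 0, 1, 0),
        3: ([("akg", 3, 1)], 0, 1, 0),
        4: ([("akg", 3, 1)], 1, 0, 0),
        5: ([("akg", 3, 1)], 1, 0, 0, 1),        # 4x-aKG excluded (declared)
    })
    ch += _map_channels("F10", "cit", 6, {
        0: ([("accoa", 0, 1), ("mal", 0, 1)], 0, 0, 0),
        3: ([("accoa", 0, 1), ("mal", 3, 1)], 0, 0, 0),
        4: ([("accoa", 0, 1), ("mal", 4, 1)], 0, 0, 0),
        5: ([("accoa", 2, 1), ("mal", 3, 1)], 0, 0, 0),
    })
    ch += _carry("F3", "fa", "accoa", [0, 2])
    ch += _carry("fa_syn", "accoa", "fa", [0, 2])
    ch += _map_channels("F11", "akg", 5, {
        0: ([("cit", 0, 1)], 0, 0, 1),
        3: ([("cit", 3, 1)], 0, 0, 1),
        5: ([("cit", 5, 1)], 0, 0, 1),
    })
    mixer = [
        {"flux": "Y", "source": "pyr", "map": {"0": 0}, "unlabeled_gain": 1},
        {"flux": "Z", "source": "mal", "map": {"0": 0, "3": 3, "4": 4},
         "unlabeled_gain": 0},
    ]
    return {"entry": "gln_medium",
            "external_dists": {"glc_medium": {"0": 1.0}, "gln_medium": {"5": 1.0}},
            "states": states, "channels": ch, "mixers": {"oaa": mixer}}


def default_config() -> dict[str, Any]:
    """Full central-carbon network configuration as a plain dict."""
    metabolites = []
    for name, carbons, extra in _METABOLITES:
        entry = {"name": name, "carbons": carbons}
        entry.update(extra)
        metabolites.append(entry)
    cfg = {
        "name": "central_carbon",
        "version": 1,
        "metabolites": metabolites,
        "externals": dict(_EXTERNALS),
        "free_fluxes": list(_FREE_FLUXES),
        "rates": list(_RATES),
        "dependent_fluxes": copy.deepcopy(
            {k: {"expr": v["expr"], "node": v["node"]} for k, v in _DEPENDENT.items()}
        ),
        "derived_fluxes": copy.deepcopy(
            {k: {"expr": v["expr"], "node": v["node"]} for k, v in _DERIVED.items()}
        ),
        "reactions": [
            {"id": rid, "flux": dict(flux), "substrates": dict(subs),
             "products": dict(prods)}
            for rid, flux, subs, prods in _REACTIONS
        ],
        "exchange_reactions": ["F12_fwd", "F12_rev"],
        "tracers": {
            "U13C-glucose": _glucose_tracer(),
            "U13C-glutamine": _glutamine_tracer(),
        },
    }
    return cfg


# ---------------------------------------------------------------------------
# small didactic networks (used by tests and the pipeline demo)

def toy_branch_config(parallel: bool = False) -> dict[str, Any]:
    """A 2-pool branched network: S -> P -> Q with a biosynthetic drain.

    With ``parallel=True`` the P -> Q conversion is carried by two
    parallel fluxes ``fa`` and ``fb`` of which only the sum is
    identifiable from labeling data (a deliberate degeneracy).
    """
    if parallel:
        free = ["fa", "fb"]
        conv = [("fa", {"fa": 1}, {"P": 1}, {"Q": 1}),
                ("fb", {"fb": 1}, {"P": 1}, {"Q": 1})]
        drain_expr = {"A": 1, "fa": -1, "fb": -1}
        q_expr = {"fa": 1, "fb": 1}
        chans = [
            _ch("uptake", [("S", 3)], [("P", 3, 1)]),
            _ch("fa", [("P", 0)], [("Q", 0, 1)]),
            _ch("fa", [("P", 3)], [("Q", 3, 1)]),
            _ch("fb", [("P", 0)], [("Q", 0, 1)]),
            _ch("fb", [("P", 3)], [("Q", 3, 1)]),
        ]
    else:
        free = ["f1"]
        conv = [("f1", {"f1": 1}, {"P": 1}, {"Q": 1})]
        drain_expr = {"A": 1, "f1": -1}
        q_expr = {"f1": 1}
        chans = [
            _ch("uptake", [("S", 3)], [("P", 3, 1)]),
            _ch("f1", [("P", 0)], [("Q", 0, 1)]),
            _ch("f1", [("P", 3)], [("Q", 3, 1)]),
        ]
    return {
        "name": "toy_branch" + ("_parallel" if parallel else ""),
        "version": 1,
        "metabolites": [{"name": "P", "carbons": 3},
                        {"name": "Q", "carbons": 3}],
        "externals": {"S": 3},
        "free_fluxes": free,
        "rates": ["A"],
        "dependent_fluxes": {},
        "derived_fluxes": {
            "p_drain": {"expr": drain_expr, "node": "P"},
            "q_out": {"expr": q_expr, "node": "Q"},
        },
        "reactions": (
            [{"id": "uptake", "flux": {"A": 1}, "substrates": {"S": 1},
              "products": {"P": 1}}]
            + [{"id": rid, "flux": fx, "substrates": s, "products": pr}
               for rid, fx, s, pr in conv]
            + [{"id": "p_drain", "flux": {"p_drain": 1},
                "substrates": {"P": 1}, "products": {}},
               {"id": "q_out", "flux": {"q_out": 1},
                "substrates": {"Q": 1}, "products": {}}]),
        "tracers": {
            "U13C-S": {
                "entry": "S",
                "external_dists": {"S": {"3": 1.0}},
                "states": {"P": [0, 3], "Q": [0, 3]},
                "channels": chans,
                "mixers": {},
            },
        },
    }
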