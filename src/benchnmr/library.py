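"""Metabolite spin-system library.

The library ships as a human-editable YAML file (``data/metabolites.yaml``)
mapping metabolite keys to lists of :class:`~benchnmr.spin.SpinSystem`
subsystems, plus *composites* (e.g. total glucose = 36% α + 64% β anomers).
Transition lists are cached per (metabolite, field) since they are
concentration-independent: a spectrum at concentration *c* is the cached
one-molar transition list scaled by *c*.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

from .spin import SpinSystem, TransitionList, compute_transitions

__all__ = [
    "load_library",
    "list_metabolites",
    "get_spin_systems",
    "metabolite_transitions",
    "metabolite_t1",
    "ALPHA_ANOMER_FRACTION",
]

# equilibrium anomer abundance used throughout the quantification protocol
ALPHA_ANOMER_FRACTION = 0.36


@lru_cache(maxsize=1)
def load_library() -> dict:
    text = resources.files("benchnmr.data").joinpath("metabolites.yaml").read_text()
    return yaml.safe_load(text)


def list_metabolites() -> list:
    lib = load_library()
    return sorted(set(lib["metabolites"]) | set(lib.get("composites", {})))


def _resolve(name: str) -> dict:
    """Map a metabolite (or composite) name to {library key: molar fraction}."""
    lib = load_library()
    if name in lib["metabolites"]:
        return {name: 1.0}
    comp = lib.get("composites", {})
    if name in comp:
        return dict(comp[name]["components"])
    raise KeyError(
        f"unknown metabolite {name!r}; library entries: "
        + ", ".join(list_metabolites()))


def get_spin_systems(name: str) -> list:
    """SpinSystem subsystems for a plain (non-composite) library entry."""
    lib = load_library()
    if name not in lib["metabolites"]:
        raise KeyError(f"{name!r} is not a plain library entry")
    return [SpinSystem.from_dict(d) for d in lib["metabolites"][name]["subsystems"]]


@lru_cache(maxsize=256)
def _transitions_1M(name: str, field_MHz: float) -> tuple:
    """Per-subsystem transitions of one plain entry at unit concentration.

    Returns a tuple of (TransitionList, t1_per_group) pairs; intensities are
    in proton-equivalents (i.e. per mole of molecule).
    """
    out = []
    for sys in get_spin_systems(name):
        tl = compute_transitions(sys, field_MHz)
        out.append((tl, np.asarray(sys.t1_s, dtype=float)))
    return tuple(out)


def metabolite_transitions(name: str, field_MHz: float,
                           concentration: float = 1.0) -> TransitionList:
    """Transition list of a metabolite/composite at a molar concentration.

    Intensity units are concentration × proton-equivalents, so a TSP-style
    internal-standard ratio of two integrals is directly (cα·nα)/(cTSP·9).
    No relaxation/presaturation effects are applied here.
    """
    parts = []
    for key, frac in _resolve(name).items():
        for tl, _t1 in _transitions_1M(key, field_MHz):
            parts.append(tl.scaled(concentration * frac))
    return TransitionList.concat(parts)


def metabolite_t1(name: str, field_MHz: float) -> list:
    """Flattened (TransitionList, per-group T1) pairs, fraction-weighted."""
    out = []
    for key, frac in _resolve(name).items():
        for tl, t1 in _transitions_1M(key, field_MHz):
            out.append((tl.scaled(frac), t1))
    return out
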