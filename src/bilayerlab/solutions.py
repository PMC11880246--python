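"""Standard bilayer bath configurations used throughout the package.

Three recording configurations recur in TMEM41B bilayer work and serve as
the package's reference conditions (HEPES buffer is omitted — it carries
no permeant ion):

* an asymmetric KCl gradient, 500 mM cis : 50 mM trans;
* a pure CaCl2 gradient, 150 mM cis : 15 mM trans;
* a K+/Ca2+ mixture, 500 KCl + 10 CaCl2 cis : 50 KCl + 100 CaCl2 trans.

Each factory returns a :class:`~bilayerlab.electrochem.BathPair`; pass
``rt_over_f`` (mV) or ``temperature_K`` to fix the thermal voltage.
"""

from __future__ import annotations

from typing import Mapping

from .electrochem import BathPair

__all__ = [
    "kcl_gradient",
    "cacl2_gradient",
    "k_ca_mixture",
    "bath_from_config",
]


def kcl_gradient(
    cis_mM: float = 500.0,
    trans_mM: float = 50.0,
    permeabilities: Mapping[str, float] | None = None,
    **kwargs,
) -> BathPair:
    """Asymmetric KCl bath (default 500:50 mM)."""
    if permeabilities is None:
        permeabilities = {"K+": 1.0}
    return BathPair.from_salts(
        cis={"KCl": cis_mM}, trans={"KCl": trans_mM},
        permeabilities=permeabilities, **kwargs,
    )


def cacl2_gradient(
    cis_mM: float = 150.0,
    trans_mM: float = 15.0,
    permeabilities: Mapping[str, float] | None = None,
    **kwargs,
) -> BathPair:
    """Pure CaCl2 bath (default 150:15 mM)."""
    if permeabilities is None:
        permeabilities = {"Ca2+": 1.0}
    return BathPair.from_salts(
        cis={"CaCl2": cis_mM}, trans={"CaCl2": trans_mM},
        permeabilities=permeabilities, **kwargs,
    )


def k_ca_mixture(
    cis_kcl_mM: float = 500.0,
    cis_cacl2_mM: float = 10.0,
    trans_kcl_mM: float = 50.0,
    trans_cacl2_mM: float = 100.0,
    permeabilities: Mapping[str, float] | None = None,
    **kwargs,
) -> BathPair:
    """K+/Ca2+ mixture bath (default 500 K + 10 Ca : 50 K + 100 Ca)."""
    if permeabilities is None:
        permeabilities = {"K+": 1.0, "Ca2+": 1.0}
    return BathPair.from_salts(
        cis={"KCl": cis_kcl_mM, "CaCl2": cis_cacl2_mM},
        trans={"KCl": trans_kcl_mM, "CaCl2": trans_cacl2_mM},
        permeabilities=permeabilities, **kwargs,
    )


def bath_from_config(config: Mapping) -> BathPair:
    """Build a bath from a config mapping with keys ``cis``, ``trans``
    (salt -> mM), optional ``permeabilities``, and either ``temperature_K``
    or ``rt_over_f_mV``."""
    return BathPair.from_salts(
        cis=config["cis"],
        trans=config["trans"],
        permeabilities=config.get("permeabilities"),
        temperature_K=config.get("temperature_K"),
        rt_over_f=config.get("rt_over_f_mV"),
    )
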