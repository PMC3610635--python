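"""Receptor-chain constructs, kinetic parameters and concentration totals.

The domain vocabulary: an :class:`ITAMSpec` describes one ITAM (two
phosphorylation sites) with its ZAP-70 binding kinetics and optional
per-ITAM enzyme off-rate overrides; a :class:`ChainSpec` is an ordered
list of ITAMs (membrane-distal first — the first ITAM in the list is
phosphorylated first under the sequential scheme) together with the
phosphorylation scheme and a ZAP-70 on/off switch.

A registry of named presets covers the receptor variants commonly
compared in this model family: the wild-type zeta chain (``z123``,
ZAP-70 affinity increasing in the direction of phosphorylation),
truncations (``zX23``, ``zXX3``), uniform-affinity duplications
(``z111``/``z222``/``z333``), the order-switched ``z321``, the random
phosphorylation variant, single- and triple-ITAM CAR signaling domains
built from the Fc-epsilon-RI gamma and beta ITAMs, and the
differential-enzyme (no-ZAP) variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "ITAMSpec",
    "ChainSpec",
    "RateSet",
    "ConcentrationTotals",
    "ValidationError",
    "build_chain_spec",
    "preset_construct",
    "preset_names",
    "chain_spec_to_dict",
    "chain_spec_from_dict",
]

MAX_ITAMS = 4
SITES_PER_ITAM = 2

SCHEMES = ("sequential", "random")

#: Anchor for the ZAP-70 unbinding-rate ladder: the middle-affinity ITAM
#: (zeta-2) unbinds at 1 /s, and affinity steps 10-fold per ITAM, so the
#: wild-type distal-to-proximal koff ladder is (10, 1, 0.1) /s.
ZAP_KOFF_Z1 = 0.1
ZAP_KOFF_Z2 = 1.0
ZAP_KOFF_Z3 = 10.0
#: Fc-epsilon-RI gamma/beta ITAMs bind ZAP-70 10x / 100x weaker than zeta-1.
ZAP_KOFF_FCERI_GAMMA = 10.0 * ZAP_KOFF_Z1
ZAP_KOFF_FCERI_BETA = 100.0 * ZAP_KOFF_Z1

DEFAULT_KON = 0.1  # uM^-1 s^-1, enzyme association
#: ZAP-70 association is taken diffusion-limited (1e8 M^-1 s^-1): with the
#: 1 /s anchor this gives a 10 nM dissociation constant for the middle
#: ITAM, in the range reported for tandem-SH2 / doubly phosphorylated
#: ITAM binding, and puts ZAP-70 docking in the near-saturating regime
#: in which the chain is fully ZAP-loaded when the kinase dominates.
DEFAULT_ZAP_KON = 100.0  # uM^-1 s^-1


class ValidationError(ValueError):
    """A construct or parameter failed validation; the message names the field."""


def _require_positive(name: str, value: float) -> float:
    value = float(value)
    if not value > 0:
        raise ValidationError(f"{name} must be strictly positive, got {value!r}")
    return value


@dataclass(frozen=True)
class ITAMSpec:
    """One ITAM: two phosphorylation sites plus ZAP-70 binding kinetics.

    ``kinase_koff`` / ``phosphatase_koff`` override the global enzyme
    off-rate for substrate sites on this ITAM (used for the
    differential-enzyme-affinity variants); ``None`` means use the
    global :class:`RateSet` value.
    """

    label: str
    zap_koff: float  # s^-1
    zap_kon: float = DEFAULT_ZAP_KON  # uM^-1 s^-1
    kinase_koff: Optional[float] = None  # s^-1
    phosphatase_koff: Optional[float] = None  # s^-1

    def __post_init__(self) -> None:
        if not self.label:
            raise ValidationError("label must be a non-empty identifier")
        _require_positive("zap_koff", self.zap_koff)
        _require_positive("zap_kon", self.zap_kon)
        if self.kinase_koff is not None:
            _require_positive("kinase_koff", self.kinase_koff)
        if self.phosphatase_koff is not None:
            _require_positive("phosphatase_koff", self.phosphatase_koff)


@dataclass(frozen=True)
class ChainSpec:
    """A receptor chain: ordered ITAMs (membrane-distal first), scheme, ZAP switch.

    Under ``scheme="sequential"`` the list order defines the
    phosphorylation order (first ITAM's sites first) and
    dephosphorylation proceeds in the exact reverse (last-on-first-off).
    """

    itams: tuple[ITAMSpec, ...]
    scheme: str = "sequential"
    zap_enabled: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "itams", tuple(self.itams))
        if self.scheme not in SCHEMES:
            raise ValidationError(
                f"scheme must be one of {SCHEMES}, got {self.scheme!r}"
            )
        if len(self.itams) > MAX_ITAMS:
            raise ValidationError(
                f"itams: at most {MAX_ITAMS} ITAMs supported, got {len(self.itams)}"
            )
        labels = [it.label for it in self.itams]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"itams: duplicate labels in {labels}")

    @property
    def n_itams(self) -> int:
        return len(self.itams)

    @property
    def n_sites(self) -> int:
        return SITES_PER_ITAM * len(self.itams)


@dataclass(frozen=True)
class RateSet:
    """Global enzyme rate constants; defaults make kinase and phosphatase
    kinetically identical."""

    kinase_kon: float = DEFAULT_KON  # uM^-1 s^-1
    kinase_koff: float = 1.0  # s^-1
    kinase_kcat: float = 1.0  # s^-1
    phosphatase_kon: float = DEFAULT_KON  # uM^-1 s^-1
    phosphatase_koff: float = 1.0  # s^-1
    phosphatase_kcat: float = 1.0  # s^-1

    def __post_init__(self) -> None:
        for name in (
            "kinase_kon",
            "kinase_koff",
            "kinase_kcat",
            "phosphatase_kon",
            "phosphatase_koff",
            "phosphatase_kcat",
        ):
            _require_positive(name, getattr(self, name))


@dataclass(frozen=True)
class ConcentrationTotals:
    """Total concentrations (uM): chain substrate, kinase E, phosphatase F, ZAP-70.

    Defaults put both enzymes in excess of the chain and ZAP-70 in
    excess of the 3-per-chain binding capacity.
    """

    chain_total: float = 0.5
    kinase_total: float = 1.0
    phosphatase_total: float = 1.0
    zap_total: float = 6.0

    def __post_init__(self) -> None:
        for name in ("chain_total", "kinase_total", "phosphatase_total", "zap_total"):
            value = float(getattr(self, name))
            if value < 0:
                raise ValidationError(f"{name} must be >= 0, got {value!r}")


def build_chain_spec(
    itam_descriptors: Iterable[Mapping | ITAMSpec],
    scheme: str = "sequential",
    zap_enabled: bool = True,
    name: str = "",
) -> ChainSpec:
    """Build and validate a :class:`ChainSpec` from ITAM descriptors.

    Each descriptor is an :class:`ITAMSpec` or a mapping with at least
    ``label`` and ``zap_koff``; the ZAP on-rate defaults to the shared
    value unless explicitly overridden.
    """
    itams = []
    for i, desc in enumerate(itam_descriptors):
        if isinstance(desc, ITAMSpec):
            itams.append(desc)
        else:
            try:
                itams.append(ITAMSpec(**dict(desc)))
            except TypeError as exc:
                raise ValidationError(f"itams[{i}]: {exc}") from exc
    return ChainSpec(tuple(itams), scheme=scheme, zap_enabled=zap_enabled, name=name)


def _ladder(labels: Sequence[str], koffs: Sequence[float], **kw) -> tuple[ITAMSpec, ...]:
    return tuple(ITAMSpec(label=l, zap_koff=k, **kw) for l, k in zip(labels, koffs))


def _base_presets() -> dict[str, ChainSpec]:
    z3, z2, z1 = ZAP_KOFF_Z3, ZAP_KOFF_Z2, ZAP_KOFF_Z1
    g, b = ZAP_KOFF_FCERI_GAMMA, ZAP_KOFF_FCERI_BETA
    presets = {
        # wild type: affinity increases in the direction of phosphorylation
        "z123": _ladder(("z3", "z2", "z1"), (z3, z2, z1)),
        "zX23": _ladder(("z3", "z2"), (z3, z2)),
        "zXX3": _ladder(("z3",), (z3,)),
        "z111": _ladder(("z1a", "z1b", "z1c"), (z1, z1, z1)),
        "z222": _ladder(("z2a", "z2b", "z2c"), (z2, z2, z2)),
        "z333": _ladder(("z3a", "z3b", "z3c"), (z3, z3, z3)),
        "z321": _ladder(("z1", "z2", "z3"), (z1, z2, z3)),
        "z1_single": _ladder(("z1",), (z1,)),
        "fceri_gamma_single": _ladder(("fcg",), (g,)),
        "fceri_beta_single": _ladder(("fcb",), (b,)),
        "fceri_gamma_x3": _ladder(("fcg_a", "fcg_b", "fcg_c"), (g, g, g)),
        "fceri_beta_x3": _ladder(("fcb_a", "fcb_b", "fcb_c"), (b, b, b)),
    }
    specs = {
        name: ChainSpec(itams, scheme="sequential", zap_enabled=True, name=name)
        for name, itams in presets.items()
    }
    specs["z123_random"] = ChainSpec(
        presets["z123"], scheme="random", zap_enabled=True, name="z123_random"
    )
    # differential-enzyme variants (no ZAP): kinase affinity increases
    # distal->proximal, phosphatase affinity increases proximal->distal,
    # 10-fold steps anchored at the global off-rate on the middle ITAM.
    kin_lad = (10.0, 1.0, 0.1)
    pho_lad = (0.1, 1.0, 10.0)
    for name, kin, pho in (
        ("figS2_none", (None,) * 3, (None,) * 3),
        ("figS2_lck", kin_lad, (None,) * 3),
        ("figS2_cd45", (None,) * 3, pho_lad),
        ("figS2_both", kin_lad, pho_lad),
    ):
        itams = tuple(
            ITAMSpec(label=l, zap_koff=k, kinase_koff=kk, phosphatase_koff=pk)
            for l, k, kk, pk in zip(("z3", "z2", "z1"), (z3, z2, z1), kin, pho)
        )
        specs[name] = ChainSpec(itams, scheme="sequential", zap_enabled=False, name=name)
    return specs


_PRESETS = _base_presets()


def preset_names() -> list[str]:
    """All preset construct names, including the ``_nozap`` variants."""
    names = sorted(_PRESETS)
    names += [n + "_nozap" for n in sorted(_PRESETS) if _PRESETS[n].zap_enabled]
    return names


def preset_construct(name: str) -> ChainSpec:
    """Look up a named preset construct.

    Any ZAP-enabled preset also exists with a ``_nozap`` suffix, which
    disables ZAP-70 binding but leaves the chain unchanged.
    """
    base, nozap = name, False
    if name.endswith("_nozap"):
        base, nozap = name[: -len("_nozap")], True
    if base not in _PRESETS:
        raise ValidationError(
            f"unknown construct {name!r}; known: {', '.join(preset_names())}"
        )
    spec = _PRESETS[base]
    if nozap:
        spec = replace(spec, zap_enabled=False, name=name)
    return spec


# ---------------------------------------------------------------------------
# config (de)serialization


def chain_spec_to_dict(spec: ChainSpec) -> dict:
    return {
        "name": spec.name,
        "scheme": spec.scheme,
        "zap_enabled": spec.zap_enabled,
        "itams": [
            {
                "label": it.label,
                "zap_koff": it.zap_koff,
                "zap_kon": it.zap_kon,
                "kinase_koff": it.kinase_koff,
                "phosphatase_koff": it.phosphatase_koff,
            }
            for it in spec.itams
        ],
    }


def chain_spec_from_dict(d: Mapping) -> ChainSpec:
    itams = []
    for item in d.get("itams", []):
        item = {k: v for k, v in dict(item).items() if v is not None}
        itams.append(item)
    return build_chain_spec(
        itams,
        scheme=d.get("scheme", "sequential"),
        zap_enabled=bool(d.get("zap_enabled", True)),
        name=d.get("name", ""),
    )
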