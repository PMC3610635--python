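"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's breadth-first generator: species
are enumerated by explicit nested loops over every combination of site
occupancy, ZAP occupancy and bound enzyme, filtered by literal
transcriptions of the eligibility rules, and reactions are produced by
applying each rule to every enumerated state.  The single-ITAM
steady-state oracle writes out the nine mass-action balance equations
of the two-site modification cycle by hand and root-finds them.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import root

from itamnet.constructs import ChainSpec, RateSet
from itamnet.network import KINASE, PHOSPHATASE, ZAP, Reaction, Species


def _full_itams(sites: int, n_itams: int) -> list[int]:
    return [
        j for j in range(n_itams)
        if sites >> (2 * j) & 1 and sites >> (2 * j + 1) & 1
    ]


def _valid_sequential_sites(mask: int, n_sites: int) -> bool:
    # a contiguous phosphorylated prefix: no set bit above an unset bit
    seen_unset = False
    for i in range(n_sites):
        bit = mask >> i & 1
        if not bit:
            seen_unset = True
        elif seen_unset:
            return False
    return True


def brute_force_species(spec: ChainSpec) -> set[Species]:
    """All valid chain states by exhaustive nested enumeration, plus free molecules."""
    n, ns = spec.n_itams, spec.n_sites
    out: set[Species] = set()
    enzyme_options: list = [None]
    for site in range(ns):
        enzyme_options.append((KINASE, site))
        enzyme_options.append((PHOSPHATASE, site))
    for sites in range(1 << ns):
        if spec.scheme == "sequential" and not _valid_sequential_sites(sites, ns):
            continue
        level = bin(sites).count("1")
        full = _full_itams(sites, n)
        for zap_bits in itertools.product([0, 1], repeat=n):
            zap = sum(b << j for j, b in enumerate(zap_bits))
            if not spec.zap_enabled and zap:
                continue
            if any(b and j not in full for j, b in enumerate(zap_bits)):
                continue
            for enz in enzyme_options:
                if enz is not None:
                    kind, site = enz
                    phosphorylated = bool(sites >> site & 1)
                    if kind == KINASE:
                        if phosphorylated:
                            continue
                        if spec.scheme == "sequential" and site != level:
                            continue
                    else:
                        if not phosphorylated:
                            continue
                        if spec.scheme == "sequential" and site != level - 1:
                            continue
                        if zap >> (site // 2) & 1:
                            continue
                out.add(Species("chain", sites, zap, enz))
    out |= {Species(KINASE), Species(PHOSPHATASE), Species(ZAP)}
    return out


def brute_force_reactions(spec: ChainSpec, rates: RateSet) -> set[Reaction]:
    """Apply every rule literally to every enumerated state."""
    n, ns = spec.n_itams, spec.n_sites
    free_k, free_p, free_z = Species(KINASE), Species(PHOSPHATASE), Species(ZAP)
    rxns: set[Reaction] = set()
    for s in brute_force_species(spec):
        if s.kind != "chain":
            continue
        level = bin(s.sites).count("1")
        full = _full_itams(s.sites, n)
        if s.enzyme is None:
            for site in range(ns):
                phosphorylated = bool(s.sites >> site & 1)
                if not phosphorylated and (
                    spec.scheme == "random" or site == level
                ):
                    rxns.add(Reaction(
                        (s, free_k),
                        (Species("chain", s.sites, s.zap, (KINASE, site)),),
                        rates.kinase_kon, "kinase_bind"))
                if (
                    phosphorylated
                    and (spec.scheme == "random" or site == level - 1)
                    and not s.zap >> (site // 2) & 1
                ):
                    rxns.add(Reaction(
                        (s, free_p),
                        (Species("chain", s.sites, s.zap, (PHOSPHATASE, site)),),
                        rates.phosphatase_kon, "phosphatase_bind"))
        else:
            kind, site = s.enzyme
            bare = Species("chain", s.sites, s.zap, None)
            itam = spec.itams[site // 2]
            if kind == KINASE:
                koff = itam.kinase_koff or rates.kinase_koff
                rxns.add(Reaction((s,), (bare, free_k), koff, "kinase_unbind"))
                prod = Species("chain", s.sites | 1 << site, s.zap, None)
                rxns.add(Reaction((s,), (prod, free_k), rates.kinase_kcat, "kinase_cat"))
            else:
                koff = itam.phosphatase_koff or rates.phosphatase_koff
                rxns.add(Reaction((s,), (bare, free_p), koff, "phosphatase_unbind"))
                prod = Species("chain", s.sites & ~(1 << site), s.zap, None)
                rxns.add(Reaction(
                    (s,), (prod, free_p), rates.phosphatase_kcat, "phosphatase_cat"))
        if spec.zap_enabled:
            p_itam = (
                s.enzyme[1] // 2
                if s.enzyme is not None and s.enzyme[0] == PHOSPHATASE
                else -1
            )
            for j in full:
                if not s.zap >> j & 1 and j != p_itam:
                    rxns.add(Reaction(
                        (s, free_z),
                        (Species("chain", s.sites, s.zap | 1 << j, s.enzyme),),
                        spec.itams[j].zap_kon, "zap_bind"))
            for j in range(n):
                if s.zap >> j & 1:
                    rxns.add(Reaction(
                        (s,),
                        (Species("chain", s.sites, s.zap & ~(1 << j), s.enzyme), free_z),
                        spec.itams[j].zap_koff, "zap_unbind"))
    return rxns


def single_itam_phospho_oracle(
    rates: RateSet,
    chain_total: float,
    kinase_total: float,
    phosphatase_total: float,
) -> float:
    """Total phosphorylation of a single-ITAM chain without ZAP, solved
    by root-finding the hand-written balance equations.

    Species: C0, C1, C2 (0/1/2 phosphates), the four enzyme complexes
    C0K, C1K (kinase on site 0/1) and C1P, C2P (phosphatase on site
    0/1), plus free kinase E and phosphatase F.  Sequential order makes
    site 0 first on, last off.
    """
    a_k, d_k, k_k = rates.kinase_kon, rates.kinase_koff, rates.kinase_kcat
    a_p, d_p, k_p = rates.phosphatase_kon, rates.phosphatase_koff, rates.phosphatase_kcat

    def equations(v):
        c0, c1, c2, c0k, c1k, c1p, c2p, e, f = v
        return [
            -a_k * c0 * e + d_k * c0k + k_p * c1p,                    # C0
            -a_k * c1 * e - a_p * c1 * f + d_k * c1k + d_p * c1p
            + k_k * c0k + k_p * c2p,                                  # C1
            -a_p * c2 * f + d_p * c2p + k_k * c1k,                    # C2
            a_k * c0 * e - (d_k + k_k) * c0k,                         # C0K
            a_k * c1 * e - (d_k + k_k) * c1k,                         # C1K
            a_p * c1 * f - (d_p + k_p) * c1p,                         # C1P
            c0 + c1 + c2 + c0k + c1k + c1p + c2p - chain_total,       # chain cons.
            e + c0k + c1k - kinase_total,                             # kinase cons.
            f + c1p + c2p - phosphatase_total,                        # phosphatase cons.
        ]

    guess = np.array([chain_total, 0, 0, 0, 0, 0, 0, kinase_total, phosphatase_total],
                     dtype=float)
    sol = root(equations, guess, method="hybr", tol=1e-14)
    assert sol.success, sol.message
    c0, c1, c2, c0k, c1k, c1p, c2p, e, f = sol.x
    return (c1 + c1k + c1p) + 2.0 * (c2 + c2p)
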