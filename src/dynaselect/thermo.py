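"""Boltzmann statistics over competing transition states and pure-TST selectivity.

Relative populations of competing transition-state conformers follow
w_i ∝ exp(-ΔΔG‡_i / RT).  Before any selectivity analysis the ensemble is
pruned to the low-energy conformers that jointly carry 99% of the Boltzmann
population (renormalized), and each first transition state is subjected to
an energy check: the dynamic (trajectory-stream) analysis is only trusted
when every second transition state downstream lies strictly below the first
in Gibbs free energy — otherwise the branch falls back to transition state
theory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_TEMPERATURE_K, R_KCAL_MOL_K
from .errors import ValidationError
from .io_qc import StationaryPoint


@dataclass
class BoltzmannEnsemble:
    """Competing members with relative barriers (kcal/mol) and normalized weights.

    Members are stored sorted by increasing ΔΔG‡, relative to the lowest
    member (which therefore sits at ΔΔG‡ = 0).
    """

    labels: list[str]
    rel_energies: np.ndarray  # ΔΔG‡, kcal/mol, ascending, min = 0
    temperature: float
    weights: np.ndarray

    @property
    def members(self) -> list[tuple[str, float]]:
        return list(zip(self.labels, self.rel_energies.tolist()))


@dataclass
class MethodDecision:
    """Which analysis a pathway gets (VRAI or TST fallback) and why."""

    pathway_label: str
    method: str  # "VRAI" | "TST_fallback"
    reason: str


def boltzmann_weights(
    energies: list[float] | np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE_K,
    labels: list[str] | None = None,
) -> BoltzmannEnsemble:
    """Normalized Boltzmann populations for relative free energies (kcal/mol)."""
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise ValidationError("boltzmann_weights needs at least one energy")
    if not np.all(np.isfinite(e)):
        raise ValidationError("non-finite energy in Boltzmann ensemble")
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    if labels is None:
        labels = [str(i) for i in range(e.size)]
    order = np.argsort(e, kind="stable")
    e = e[order] - e[order[0]]
    labels = [labels[i] for i in order]
    w = np.exp(-e / (R_KCAL_MOL_K * temperature))
    w /= w.sum()
    return BoltzmannEnsemble(labels, e, float(temperature), w)


def select_top_coverage(
    ensemble: BoltzmannEnsemble, coverage: float = 0.99
) -> BoltzmannEnsemble:
    """Smallest low-energy prefix whose cumulative weight reaches *coverage*.

    Members tied in ΔΔG‡ with the last retained member are also retained, so
    the result does not depend on their input order.  Retained weights are
    renormalized to sum to 1.
    """
    if not 0 < coverage <= 1:
        raise ValidationError("coverage must lie in (0, 1]")
    cum = np.cumsum(ensemble.weights)
    k = int(np.searchsorted(cum, coverage - 1e-12)) + 1
    k = min(k, len(ensemble.weights))
    while k < len(ensemble.weights) and np.isclose(
        ensemble.rel_energies[k], ensemble.rel_energies[k - 1], atol=1e-12
    ):
        k += 1
    w = ensemble.weights[:k] / ensemble.weights[:k].sum()
    return BoltzmannEnsemble(
        ensemble.labels[:k], ensemble.rel_energies[:k].copy(), ensemble.temperature, w
    )


def energy_check(
    ts1: StationaryPoint, downstream_ts2s: list[StationaryPoint]
) -> MethodDecision:
    """Trust dynamics only if every downstream TS lies strictly below TS1.

    An empty downstream list (all channels barrierless) passes vacuously.
    Equality is treated as a failure: the conservative branch is TST.
    """
    offenders = [
        t.label for t in downstream_ts2s if t.gibbs_free_energy >= ts1.gibbs_free_energy
    ]
    if offenders:
        return MethodDecision(
            ts1.label,
            "TST_fallback",
            "downstream TS not below TS1: " + ", ".join(sorted(offenders)),
        )
    return MethodDecision(
        ts1.label, "VRAI", "all downstream TSs below TS1 in Gibbs free energy"
    )


def tst_product_percentages(network, temperature: float = DEFAULT_TEMPERATURE_K,
                            coverage: float = 0.99):
    """Product percentages from transition state theory only.

    Thin wrapper over the pipeline in ``tst_only`` mode (kept here because
    TST is a complete selectivity model on its own).
    """
    from .pipeline import RunSettings, run_selectivity_pipeline

    settings = RunSettings(temperature_K=temperature, coverage_fraction=coverage,
                           mode="tst_only")
    return run_selectivity_pipeline(network, settings)
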