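"""Selectivity pipeline: Boltzmann populations × stream partitions → product percentages.

The full calculation mirrors the Sankey-diagram arithmetic of the method:

1. Boltzmann-weight the competing first transition states (TS1 conformers)
   and keep the low-energy set carrying 99% of the population (renormalized).
2. Resolve each retained TS1 branch:
   * ``with_vrai`` — run the energy check; if every downstream TS lies below
     the TS1, partition the branch by the trajectory-stream analysis over
     all products reachable from its intermediate (including channels
     through a stable shoulder intermediate); otherwise fall back to
     Boltzmann weighting over the second transition states.
   * ``tst_only`` — always Boltzmann-weight the second transition states
     (with 99% coverage inside each branch).
   Barrierless channels carry their full branch weight to their product.
3. When a dynamic complexation stage is declared (a TS0 whose stream
   partition splits flow among intermediate stereochemistry channels before
   TS1-level resolution), the TS1 ensemble is Boltzmann-weighted *within*
   each stereochemistry group and scaled by the stage-0 fraction.
4. Each product percentage is the sum of (TS1 population × branch fraction),
   scaled to 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE_K
from .errors import ValidationError
from .io_qc import ReactionNetwork, StationaryPoint
from .thermo import MethodDecision, boltzmann_weights, energy_check, select_top_coverage
from .vrai_core import DEFAULT_BOND_THRESHOLD_A, predict_multi_product_ratio


@dataclass
class RunSettings:
    """Tunable hyperparameters of one pipeline run."""

    temperature_K: float = DEFAULT_TEMPERATURE_K
    coverage_fraction: float = 0.99
    width_model: str = "zero_point"
    bond_threshold_A: float = DEFAULT_BOND_THRESHOLD_A
    mode: str = "with_vrai"  # "tst_only" | "with_vrai"

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValidationError("temperature_K must be positive")
        if not 0 < self.coverage_fraction <= 1:
            raise ValidationError("coverage_fraction must lie in (0, 1]")
        if self.mode not in ("tst_only", "with_vrai"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.width_model not in ("zero_point", "thermal"):
            raise ValidationError(f"unknown width_model {self.width_model!r}")

    def to_dict(self) -> dict:
        return {
            "temperature_K": self.temperature_K,
            "coverage_fraction": self.coverage_fraction,
            "width_model": self.width_model,
            "bond_threshold_A": self.bond_threshold_A,
            "mode": self.mode,
        }


@dataclass
class PathwayFlow:
    """One TS1 branch: its population and how it splits among products."""

    ts1_label: str
    ts1_population: float
    branch_resolutions: dict[str, float]
    contributions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = sum(self.branch_resolutions.values())
        if abs(s - 1.0) > 1e-9:
            raise ValidationError(f"{self.ts1_label}: branch fractions sum to {s}")
        if not self.contributions:
            self.contributions = {
                k: self.ts1_population * f for k, f in self.branch_resolutions.items()
            }


@dataclass
class ProductDistribution:
    """Final percentages per (species, stereochem), with per-pathway detail."""

    percentages: dict[tuple[str, str | None], float]
    label_percentages: dict[str, float]
    method_per_pathway: list[MethodDecision]
    pathway_flows: list[PathwayFlow]
    settings: RunSettings
    mae_vs_experiment: float | None = None
    catalog: dict[str, tuple[str, str | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.percentages.values())
        if abs(total - 100.0) > 1e-6:
            raise ValidationError(f"percentages sum to {total}, not 100")

    def formatted(self) -> dict[str, float]:
        """Percentages keyed by human-readable product identity strings."""
        out = {}
        for (species, stereo), pct in sorted(self.percentages.items()):
            key = f"{species} ({stereo})" if stereo else species
            out[key] = pct
        return out

    def sankey_edges(self) -> list[tuple[str, str, float]]:
        """Flow edge list (source, target, percent) for Sankey-style plotting."""
        edges = []
        for flow in self.pathway_flows:
            edges.append(("TS1 ensemble", flow.ts1_label, 100.0 * flow.ts1_population))
            for product, contrib in flow.contributions.items():
                if contrib > 0:
                    edges.append((flow.ts1_label, product, 100.0 * contrib))
        return edges


# ---------------------------------------------------------------------------
# Branch resolution
# ---------------------------------------------------------------------------

def _direct_products(network: ReactionNetwork, ts1: StationaryPoint) -> list[StationaryPoint]:
    return [
        p for p in network.successors(ts1.label)
        if p.role == "product"
        and network.channel_kind.get((ts1.label, p.label), "via_TS2")
        == "barrierless_direct"
    ]


def _tst_flow(
    network: ReactionNetwork,
    label: str,
    flow: float,
    settings: RunSettings,
    acc: dict[str, float],
) -> None:
    """Propagate flow through the pathway graph by Boltzmann-weighted TS competition."""
    point = network.points[label]
    if point.role == "product":
        acc[label] = acc.get(label, 0.0) + flow
        return
    succs = network.successors(label)
    if point.is_ts:
        if len(succs) != 1:
            raise ValidationError(
                f"{label}: a transition state must pass flow to exactly one successor"
            )
        _tst_flow(network, succs[0].label, flow, settings, acc)
        return
    # intermediate: competing transition states, else competing product wells
    ts_children = [s for s in succs if s.is_ts]
    competitors = ts_children if ts_children else succs
    if not competitors:
        raise ValidationError(f"{label}: intermediate has no outgoing channels")
    ens = select_top_coverage(
        boltzmann_weights(
            [c.gibbs_free_energy for c in competitors],
            settings.temperature_K,
            labels=[c.label for c in competitors],
        ),
        settings.coverage_fraction,
    )
    for lbl, w in zip(ens.labels, ens.weights):
        _tst_flow(network, lbl, flow * float(w), settings, acc)


def _resolve_branch(
    network: ReactionNetwork,
    ts1: StationaryPoint,
    settings: RunSettings,
) -> tuple[dict[str, float], MethodDecision]:
    """Fractions over product labels for one TS1 branch, plus the method used."""
    direct = _direct_products(network, ts1)
    intermediate = network.intermediate_of(ts1.label)

    if intermediate is None:
        # all channels barrierless: the branch weight goes straight to product(s)
        if not direct:
            raise ValidationError(f"{ts1.label}: no outgoing channels")
        decision = MethodDecision(ts1.label, "VRAI", "all channels barrierless")
        if len(direct) == 1:
            return {direct[0].label: 1.0}, decision
        ens = boltzmann_weights(
            [p.gibbs_free_energy for p in direct],
            settings.temperature_K,
            labels=[p.label for p in direct],
        )
        return dict(zip(ens.labels, map(float, ens.weights))), decision

    if settings.mode == "tst_only":
        acc: dict[str, float] = {}
        _tst_flow(network, intermediate.label, 1.0, settings, acc)
        for p in direct:
            acc[p.label] = acc.get(p.label, 0.0) + 0.0
        return acc, MethodDecision(ts1.label, "TST_fallback", "tst_only mode")

    decision = energy_check(ts1, network.ts2s_of(ts1.label))
    if decision.method == "TST_fallback":
        acc = {}
        _tst_flow(network, intermediate.label, 1.0, settings, acc)
        return acc, decision

    products = network.products_of(intermediate.label)
    for p in direct:
        if p not in products:
            products.append(p)
    products.sort(key=lambda p: p.label)
    if not products:
        raise ValidationError(f"{ts1.label}: no products reachable from its intermediate")
    if len(products) == 1:
        return {products[0].label: 1.0}, decision
    result = predict_multi_product_ratio(
        ts1,
        intermediate,
        products,
        temperature=settings.temperature_K,
        width_model=settings.width_model,
        bond_threshold=settings.bond_threshold_A,
    )
    return result.fractions, decision


# ---------------------------------------------------------------------------
# TS1 populations (with optional dynamic complexation stage)
# ---------------------------------------------------------------------------

def _ts1_populations(
    network: ReactionNetwork, settings: RunSettings
) -> dict[str, float]:
    ts1s = network.by_role("TS1")
    if not ts1s:
        raise ValidationError("network has no TS1 points")

    stage0 = network.stage0
    if stage0 is None or settings.mode == "tst_only":
        ens = select_top_coverage(
            boltzmann_weights(
                [t.gibbs_free_energy for t in ts1s],
                settings.temperature_K,
                labels=[t.label for t in ts1s],
            ),
            settings.coverage_fraction,
        )
        return dict(zip(ens.labels, map(float, ens.weights)))

    # dynamic complexation stage: a stream partition at TS0 splits flow among
    # intermediate stereochemistry channels, then TS1s compete inside each
    ts0 = network.points[stage0["ts0"]]
    int1 = network.points[stage0["intermediate"]]
    channels: dict[str, str] = dict(stage0["channels"])
    endpoints = [network.points[lbl] for lbl in channels.values()]
    res0 = predict_multi_product_ratio(
        ts0,
        int1,
        endpoints,
        temperature=settings.temperature_K,
        width_model=settings.width_model,
        bond_threshold=settings.bond_threshold_A,
    )
    channel_fraction = {key: res0.fractions[lbl] for key, lbl in channels.items()}

    populations: dict[str, float] = {}
    for key, frac in channel_fraction.items():
        group = [t for t in ts1s if t.stereochem == key]
        if not group:
            raise ValidationError(f"stage0 channel {key!r} matches no TS1 stereochemistry")
        ens = select_top_coverage(
            boltzmann_weights(
                [t.gibbs_free_energy for t in group],
                settings.temperature_K,
                labels=[t.label for t in group],
            ),
            settings.coverage_fraction,
        )
        for lbl, w in zip(ens.labels, ens.weights):
            populations[lbl] = frac * float(w)
    unmatched = [t.label for t in ts1s if t.stereochem not in channel_fraction]
    if unmatched:
        raise ValidationError(
            "TS1s outside every stage0 channel: " + ", ".join(sorted(unmatched))
        )
    return populations


# ---------------------------------------------------------------------------
# Entry points
# ---------------------------------------------------------------------------

def run_selectivity_pipeline(
    network: ReactionNetwork, settings: RunSettings | None = None
) -> ProductDistribution:
    """Full product-percentage calculation over a reaction network."""
    settings = settings or RunSettings()
    populations = _ts1_populations(network, settings)

    flows: list[PathwayFlow] = []
    decisions: list[MethodDecision] = []
    totals: dict[str, float] = {}
    for lbl, pop in populations.items():
        ts1 = network.points[lbl]
        fractions, decision = _resolve_branch(network, ts1, settings)
        decisions.append(decision)
        flows.append(PathwayFlow(lbl, pop, fractions))
        for product, frac in fractions.items():
            totals[product] = totals.get(product, 0.0) + pop * frac

    scale = 100.0 / sum(totals.values())
    label_pct = {lbl: 0.0 for lbl in network.product_catalog}
    for lbl, v in totals.items():
        label_pct[lbl] = v * scale

    identity_pct: dict[tuple[str, str | None], float] = {}
    for lbl, identity in network.product_catalog.items():
        identity_pct[identity] = identity_pct.get(identity, 0.0) + label_pct[lbl]

    dist = ProductDistribution(
        percentages=identity_pct,
        label_percentages=label_pct,
        method_per_pathway=decisions,
        pathway_flows=flows,
        settings=settings,
        catalog=dict(network.product_catalog),
    )
    if network.experimental_percentages is not None:
        dist.mae_vs_experiment = mae_vs_experiment(dist, network.experimental_percentages)
    return dist


def write_sankey_csv(distribution: ProductDistribution, path) -> None:
    """Write the flow edge list as CSV (source, target, flow) for plotting."""
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "flow"])
        for source, target, flow in distribution.sankey_edges():
            writer.writerow([source, target, f"{flow:.6f}"])


def write_distribution_csv(distribution: ProductDistribution, path) -> None:
    """Write per-product percentages as CSV (label, species, stereochem, percent)."""
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "species", "stereochem", "percent"])
        for label, pct in sorted(distribution.label_percentages.items()):
            species, stereo = distribution.catalog.get(label, (label, None))
            writer.writerow([label, species, stereo or "", f"{pct:.6f}"])


def mae_vs_experiment(
    distribution: ProductDistribution, experimental: dict[str, float]
) -> float:
    """Mean absolute error (percentage points) against experimental percentages.

    ``experimental`` is keyed by product label; it must cover exactly the
    calculated catalog.
    """
    calc = distribution.label_percentages
    missing = sorted(set(calc) - set(experimental))
    extra = sorted(set(experimental) - set(calc))
    if missing or extra:
        raise ValidationError(
            f"experimental/calculated catalogs differ; missing={missing}, extra={extra}"
        )
    return float(np.mean([abs(calc[k] - experimental[k]) for k in calc]))
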