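"""Reaction-network generation by iterated rule application.

Starting from seed structures, every enzyme rule is applied to every
retained structure; products below the permethylated-mass cutoff are added
and the process repeats until no new reaction appears.  With pruning
enabled, generation is interleaved with a rough abundance estimate
(linearized reactor kinetics under the reference enzyme profile): after
each batch of newly discovered structures, structures whose estimated
maximum relative concentration falls below the prune threshold are banned
and the closure is rebuilt from the seeds.  Banned structures stay banned,
so the loop reaches a fixed point: a closed network in which every
non-seed structure is reachable from a seed and predicted non-negligible.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from .config import EnzymeProfile, ReactorConfig, load_reference_config
from .formula import parse_formula
from .golgi import linear_abundance_estimate
from .isotopes import permethylated_mass
from .rules import (ReactionRule, adjusted_params, apply_rule_detailed,
                    load_adjustments, load_rule_table)

__all__ = ["Reaction", "ReactionNetwork", "GenerationConfig",
           "generate_network", "prune_network", "write_network",
           "read_network", "reference_generation_config"]


@dataclass(frozen=True)
class Reaction:
    enzyme: str
    rule_index: int
    substrate: str
    product: str
    cosubstrate: str | None
    coproduct: str | None
    kf: float
    Km: float
    Kmd: float


@dataclass
class ReactionNetwork:
    structures: list[str]            # unique canonical formulas, insertion order
    reactions: list[Reaction]
    seeds: list[str]

    @property
    def n_structures(self) -> int:
        return len(self.structures)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)


@dataclass
class GenerationConfig:
    seeds: list[str]
    mass_cutoff: float = 4000.0
    pruning_enabled: bool = True
    prune_threshold: float = 9.102e-7
    max_passes: int = 1000
    batch: int = 4000                # new structures between prune rounds
    rules: tuple[ReactionRule, ...] | None = None
    enzymes: EnzymeProfile | None = None      # profile for the prune estimate
    reactor: ReactorConfig | None = None
    activity_floor: float = 0.0

    def __post_init__(self):
        self.seeds = [parse_formula(s).text for s in self.seeds]
        if self.mass_cutoff <= 0:
            raise ValueError("mass_cutoff must be positive")
        if not (0.0 <= self.prune_threshold < 1.0):
            raise ValueError("prune_threshold must be in [0, 1)")
        for s in self.seeds:
            if permethylated_mass(s) > self.mass_cutoff:
                raise ValueError(f"seed {s} exceeds the mass cutoff")


def reference_generation_config(ref=None, **overrides) -> GenerationConfig:
    """GenerationConfig matching the packaged reference conditions."""
    if ref is None:
        ref = load_reference_config()
    floor = ref.generation_activity_floor
    profile = ref.enzymes.with_activity(
        {e: max(a, floor) for e, a in ref.enzymes.activity.items()})
    cfg = GenerationConfig(
        seeds=list(ref.seeds),
        mass_cutoff=ref.mass_cutoff,
        pruning_enabled=ref.pruning_enabled,
        prune_threshold=ref.prune_threshold,
        enzymes=profile,
        reactor=ref.reactor,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


class _Expander:
    """Applies all rules to one structure, with caching and a mass cutoff."""

    def __init__(self, rules, adjustments, mass_cutoff):
        self.rules = rules
        self.adjustments = adjustments
        self.mass_cutoff = mass_cutoff
        self.cache: dict[str, list[Reaction]] = {}

    def __call__(self, text: str) -> list[Reaction]:
        hit = self.cache.get(text)
        if hit is not None:
            return hit
        formula = parse_formula(text)
        out: list[Reaction] = []
        seen: set[tuple] = set()
        for rule in self.rules:
            for prod, site in apply_rule_detailed(formula, rule):
                key = (rule.index, prod.text)
                if key in seen:
                    continue
                if permethylated_mass(prod) > self.mass_cutoff:
                    continue
                seen.add(key)
                kf, Km, Kmd = adjusted_params(rule, formula, site,
                                              self.adjustments)
                out.append(Reaction(
                    enzyme=rule.enzyme, rule_index=rule.index,
                    substrate=text, product=prod.text,
                    cosubstrate=rule.donor, coproduct=rule.coproduct,
                    kf=kf, Km=Km, Kmd=Kmd))
        self.cache[text] = out
        return out


def _close(seeds, expand, banned, max_new=None, allowed=None):
    """Breadth-first closure from the seeds, skipping banned structures
    (and, when ``allowed`` is given, anything outside it).
    Returns (network, complete)."""
    structures: dict[str, None] = {}
    reactions: list[Reaction] = []
    todo = deque()
    for s in seeds:
        if s not in structures:
            structures[s] = None
            todo.append(s)
    new_count = 0
    complete = True
    while todo:
        if max_new is not None and new_count >= max_new:
            complete = False
            break
        s = todo.popleft()
        for rxn in expand(s):
            if rxn.product in banned:
                continue
            if allowed is not None and rxn.product not in allowed:
                continue
            reactions.append(rxn)
            if rxn.product not in structures:
                structures[rxn.product] = None
                todo.append(rxn.product)
                new_count += 1
    return ReactionNetwork(list(structures), reactions, list(seeds)), complete


def generate_network(config: GenerationConfig,
                     rules: tuple[ReactionRule, ...] | None = None,
                     ) -> ReactionNetwork:
    """Generate the closed (optionally pruned) reaction network."""
    rules = rules if rules is not None else (
        config.rules if config.rules is not None else load_rule_table())
    expand = _Expander(rules, load_adjustments(), config.mass_cutoff)
    banned: set[str] = set()
    seeds = config.seeds
    if not config.pruning_enabled:
        net, complete = _close(seeds, expand, banned, max_new=None)
        return net

    enzymes = config.enzymes
    reactor = config.reactor
    if enzymes is None or reactor is None:
        ref = load_reference_config()
        enzymes = enzymes or ref.enzymes
        reactor = reactor or ref.reactor

    batch = config.batch
    for _pass in range(config.max_passes):
        net, complete = _close(seeds, expand, banned, max_new=batch)
        if net.n_reactions:
            est = linear_abundance_estimate(net, enzymes, reactor)
        else:
            est = {s: 1.0 for s in net.structures}
        drop = {s for s in net.structures
                if est.get(s, 0.0) < config.prune_threshold
                and s not in seeds}
        if drop:
            banned |= drop
            continue
        if complete:
            return net
        batch *= 2
    raise RuntimeError("network generation did not reach a fixed point "
                       f"within {config.max_passes} passes")


def prune_network(network: ReactionNetwork, abundance_estimate: dict[str, float],
                  threshold: float,
                  rules: tuple[ReactionRule, ...] | None = None,
                  mass_cutoff: float = float("inf")) -> ReactionNetwork:
    """Drop structures with estimated abundance below ``threshold`` (seeds
    are always kept), remove dangling reactions, and re-close the rules over
    the survivors."""
    keep = {s for s in network.structures
            if abundance_estimate.get(s, 0.0) >= threshold}
    keep.update(network.seeds)
    rules = rules if rules is not None else load_rule_table()
    expand = _Expander(rules, load_adjustments(), mass_cutoff)
    net, _ = _close(network.seeds, expand, banned=set(), allowed=keep)
    return net


def write_network(network: ReactionNetwork, structures_path, reactions_path):
    """Export as TSV: structures (formula, permethylated sodiated mass) and
    reactions (rule, enzyme, endpoints, donors, kinetic parameters)."""
    with open(structures_path, "w", encoding="utf-8") as fh:
        fh.write("formula\tmass\n")
        for s in network.structures:
            fh.write(f"{s}\t{permethylated_mass(s):.4f}\n")
    with open(reactions_path, "w", encoding="utf-8") as fh:
        fh.write("rule_index\tenzyme\tsubstrate\tproduct\tcosubstrate\t"
                 "coproduct\tkf\tKm\tKmd\n")
        for r in network.reactions:
            fh.write(f"{r.rule_index}\t{r.enzyme}\t{r.substrate}\t{r.product}"
                     f"\t{r.cosubstrate or ''}\t{r.coproduct or ''}"
                     f"\t{r.kf:g}\t{r.Km:g}\t{r.Kmd:g}\n")


def read_network(structures_path, reactions_path,
                 seeds: list[str] | None = None) -> ReactionNetwork:
    structures = []
    with open(structures_path, encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            if line.strip():
                structures.append(line.split("\t")[0])
    reactions = []
    with open(reactions_path, encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            reactions.append(Reaction(
                enzyme=f[1], rule_index=int(f[0]), substrate=f[2],
                product=f[3], cosubstrate=f[4] or None, coproduct=f[5] or None,
                kf=float(f[6]), Km=float(f[7]), Kmd=float(f[8])))
    return ReactionNetwork(structures, reactions, seeds or structures[:1])
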