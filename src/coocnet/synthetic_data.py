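"""Synthetic two-cohort abundance tables with planted co-occurrence structure.

Real studies of gut microbial co-occurrence start from a species × sample
relative-abundance matrix (on the order of 150 bacterial species profiled in
roughly one hundred control and a few dozen disease subjects).  This module
generates tables of that shape with a *known* latent structure, so that every
downstream stage — similarity, thresholding, communities, roles, rich club,
percolation — can be validated against ground truth:

* species are partitioned into latent modules, one of which is a conserved
  "core" and one a structureless "background";
* each sample activates each module independently; members of an activated
  module are present with high probability, everything else falls back to a
  low baseline presence probability;
* present species receive log-normal abundances, the column is normalized,
  entries below a detection floor are zeroed (emulating the limited
  sensitivity of sequence-based detection) and the column is renormalized;
* a disease-style perturbation dissolves chosen modules (their members revert
  to baseline presence) and can promote chosen species to cross-module hubs
  that track overall community activity, never touching the core module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import EmptyTableError, InputError

CORE_MODULE = "core"
BACKGROUND_MODULE = "background"

__all__ = [
    "CORE_MODULE",
    "BACKGROUND_MODULE",
    "DiseasePerturbation",
    "SyntheticSpec",
    "generate_cohort",
    "apply_perturbation",
    "filter_detected_species",
    "four_module_spec",
    "hub_core_spec",
    "metahit_like_specs",
]


@dataclass(frozen=True)
class DiseasePerturbation:
    """Disease-style rewiring of the generative model.

    ``dissolved_modules`` lose their coordinated activation — members revert to
    independent background presence. ``hub_promotions`` names species whose
    presence is tied to overall module activity in a sample, which makes them
    cross-module connectors in the resulting network. ``core_preserved`` guards
    the core module from dissolution (the conserved-core observation).
    """

    dissolved_modules: frozenset = frozenset()
    hub_promotions: frozenset = frozenset()
    core_preserved: bool = True

    def __post_init__(self):
        object.__setattr__(self, "dissolved_modules", frozenset(self.dissolved_modules))
        object.__setattr__(self, "hub_promotions", frozenset(self.hub_promotions))
        if self.core_preserved and CORE_MODULE in self.dissolved_modules:
            raise InputError("cannot dissolve the core module while core_preserved=True")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic cohort.

    Parameters
    ----------
    n_species, n_samples
        Table dimensions.
    module_assignment
        Mapping species label -> latent module label. Module labels may include
        the designated ``"core"`` and ``"background"`` modules.
    module_activation_prob
        Probability that a sample activates a module (scalar applied to every
        non-background module, or a per-module mapping).
    within_module_presence_prob
        Presence probability for a member of an activated module.
    background_presence_prob
        Baseline presence probability (background module members, members of
        inactive modules, dissolved species).
    abundance_law
        ``(mu, sigma)`` of the log-normal law for present species.
    detection_floor
        Relative-abundance threshold below which an entry is zeroed before the
        final renormalization.
    hub_promotions
        Species present with ``within_module_presence_prob`` whenever *any*
        non-background module is active in the sample.
    seed
        RNG seed; per-sample substreams are derived deterministically.
    """

    n_species: int
    n_samples: int
    module_assignment: dict
    module_activation_prob: object = 0.5
    within_module_presence_prob: float = 0.9
    background_presence_prob: float = 0.05
    abundance_law: tuple = (0.0, 1.0)
    detection_floor: float = 1e-4
    hub_promotions: frozenset = frozenset()
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "module_assignment", dict(self.module_assignment))
        object.__setattr__(self, "hub_promotions", frozenset(self.hub_promotions))
        if self.n_species < 2:
            raise InputError("need at least 2 species")
        if self.n_samples < 1:
            raise InputError("need at least 1 sample")
        if len(self.module_assignment) != self.n_species:
            raise InputError("module_assignment must label every species exactly once")
        probs = [self.within_module_presence_prob, self.background_presence_prob]
        probs.extend(self._activation_probs().values())
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise InputError("probabilities must lie in [0, 1]")
        if self.detection_floor < 0:
            raise InputError("detection_floor must be non-negative")
        if self.abundance_law[1] < 0:
            raise InputError("log-normal scale must be non-negative")
        unknown = self.hub_promotions - set(self.module_assignment)
        if unknown:
            raise InputError(f"hub promotions for unknown species: {sorted(unknown)}")

    @property
    def species(self) -> list:
        return list(self.module_assignment)

    @property
    def modules(self) -> list:
        seen = dict.fromkeys(self.module_assignment.values())
        return list(seen)

    def _activation_probs(self) -> dict:
        mods = dict.fromkeys(self.module_assignment.values())
        if isinstance(self.module_activation_prob, dict):
            missing = set(mods) - set(self.module_activation_prob) - {BACKGROUND_MODULE}
            if missing:
                raise InputError(f"no activation probability for modules {sorted(missing)}")
            return {m: self.module_activation_prob.get(m, 0.0) for m in mods}
        return {m: float(self.module_activation_prob) for m in mods if m != BACKGROUND_MODULE}


def generate_cohort(spec: SyntheticSpec) -> tuple[pd.DataFrame, dict]:
    """Draw one cohort table; returns ``(table, ground_truth)``.

    The table is a species × sample DataFrame whose columns each sum to 1;
    the ground truth is the spec's module assignment, returned verbatim.
    Bit-reproducible for a fixed spec (one root seed, one derived substream
    per sample).
    """
    species = spec.species
    assignment = spec.module_assignment
    act_probs = spec._activation_probs()
    mu, sigma = spec.abundance_law
    hubs = spec.hub_promotions

    module_members = {}
    for s, m in assignment.items():
        module_members.setdefault(m, []).append(s)

    idx = {s: i for i, s in enumerate(species)}
    values = np.zeros((spec.n_species, spec.n_samples))
    root = np.random.SeedSequence(spec.seed)
    sample_streams = root.spawn(spec.n_samples)

    for j, ss in enumerate(sample_streams):
        rng = np.random.default_rng(ss)
        active = {m for m, p in act_probs.items() if rng.random() < p}
        any_active = bool(active)
        present = np.zeros(spec.n_species, dtype=bool)
        for s in species:
            m = assignment[s]
            if s in hubs:
                p = spec.within_module_presence_prob if any_active else spec.background_presence_prob
            elif m in active:
                p = spec.within_module_presence_prob
            else:
                p = spec.background_presence_prob
            present[idx[s]] = rng.random() < p
        if not present.any():
            # keep the column-sum invariant: force one uniformly chosen species
            present[rng.integers(spec.n_species)] = True
        k = int(present.sum())
        abund = np.exp(mu + sigma * rng.standard_normal(k)) if sigma > 0 else np.full(k, np.exp(mu))
        col = np.zeros(spec.n_species)
        col[present] = abund
        col /= col.sum()
        if spec.detection_floor > 0:
            floored = np.where(col < spec.detection_floor, 0.0, col)
            if floored.sum() == 0:  # everything fell below the floor; keep the top entry
                floored[np.argmax(col)] = col.max()
            col = floored / floored.sum()
        values[:, j] = col

    table = pd.DataFrame(values, index=pd.Index(species, name="species"),
                         columns=[f"S{j:03d}" for j in range(spec.n_samples)])
    return table, dict(assignment)


def apply_perturbation(spec: SyntheticSpec, pert: DiseasePerturbation) -> SyntheticSpec:
    """Return a new spec with the perturbation folded into the assignment.

    Members of dissolved modules are reassigned to the background module (so
    they revert to independent baseline presence) and promoted hubs are added
    to the spec's hub set. The input spec is never mutated.
    """
    known = set(spec.module_assignment.values())
    unknown = pert.dissolved_modules - known
    if unknown:
        raise InputError(f"unknown module labels: {sorted(unknown)}")
    if pert.core_preserved and CORE_MODULE in pert.dissolved_modules:
        raise InputError("cannot dissolve the core module while core_preserved=True")
    unknown_sp = pert.hub_promotions - set(spec.module_assignment)
    if unknown_sp:
        raise InputError(f"unknown species in hub promotions: {sorted(unknown_sp)}")
    assignment = {
        s: (BACKGROUND_MODULE if m in pert.dissolved_modules else m)
        for s, m in spec.module_assignment.items()
    }
    return replace(
        spec,
        module_assignment=assignment,
        hub_promotions=spec.hub_promotions | pert.hub_promotions,
    )


def filter_detected_species(table: pd.DataFrame, floor: float) -> pd.DataFrame:
    """Keep species reaching relative abundance >= ``floor`` in >= 1 sample.

    Emulates the common inclusion rule that a species must be convincingly
    detected in at least one subject of the study. Columns are renormalized
    after the drop.
    """
    if not 0.0 <= floor < 1.0:
        raise InputError("floor must lie in [0, 1)")
    keep = (table >= floor).any(axis=1) if floor > 0 else pd.Series(True, index=table.index)
    out = table.loc[keep]
    if out.empty:
        raise EmptyTableError(f"no species reaches abundance {floor} in any sample")
    sums = out.sum(axis=0)
    return out.div(sums.where(sums > 0, 1.0), axis=1)


# ---------------------------------------------------------------------------
# Ready-made study designs


def _block_assignment(blocks: dict) -> dict:
    assignment = {}
    for module, n in blocks.items():
        for i in range(n):
            assignment[f"{module}_{i:03d}"] = module
    return assignment


def four_module_spec(n_species: int = 120, n_samples: int = 120, *,
                     activation: float = 0.5, presence: float = 0.95,
                     background: float = 0.02, seed: int = 0) -> SyntheticSpec:
    """Four equal planted modules and no background block.

    The strong-parameter regime (presence 0.95, background 0.02, >= 100
    samples) in which the downstream pipeline is expected to recover the
    planted partition essentially perfectly.
    """
    per = n_species // 4
    sizes = [per, per, per, n_species - 3 * per]
    blocks = dict(zip([CORE_MODULE, "modB", "modC", "modD"], sizes))
    return SyntheticSpec(
        n_species=n_species,
        n_samples=n_samples,
        module_assignment=_block_assignment(blocks),
        module_activation_prob=activation,
        within_module_presence_prob=presence,
        background_presence_prob=background,
        seed=seed,
    )


def hub_core_spec(n_species: int = 120, n_samples: int = 120, *, n_hubs: int = 8,
                  seed: int = 0) -> SyntheticSpec:
    """Four planted modules plus a promoted, mutually co-occurring hub core.

    The promoted species track overall module activity and therefore
    co-occur with each other far more than degree alone predicts — a planted
    rich club. The hubs are drawn from the non-core modules.
    """
    spec = four_module_spec(n_species, n_samples, seed=seed)
    members = [s for s, m in spec.module_assignment.items() if m != CORE_MODULE]
    hubs = frozenset(members[:: max(1, len(members) // n_hubs)][:n_hubs])
    return replace(spec, hub_promotions=hubs)


def metahit_like_specs(seed: int = 0) -> tuple[SyntheticSpec, SyntheticSpec]:
    """A (healthy, disease) spec pair at the scale of the motivating study.

    150 species in five equal blocks (core, three structured modules and one
    background block), 99 control samples. The disease cohort has 25 samples,
    dissolves two of the structured modules, and promotes four species to
    cross-module hubs — mirroring the qualitative disease signature (conserved
    core, dissolved peripheral modules, newly over-connected species).
    """
    blocks = {CORE_MODULE: 30, "modB": 30, "modC": 30, "modD": 30, BACKGROUND_MODULE: 30}
    healthy = SyntheticSpec(
        n_species=150,
        n_samples=99,
        module_assignment=_block_assignment(blocks),
        module_activation_prob=0.5,
        within_module_presence_prob=0.9,
        background_presence_prob=0.05,
        seed=seed,
    )
    pert = DiseasePerturbation(
        dissolved_modules=frozenset({"modC", "modD"}),
        hub_promotions=frozenset({"modC_000", "modC_001", "modD_000", "modD_001"}),
    )
    disease = replace(apply_perturbation(healthy, pert), n_samples=25, seed=seed + 1)
    return healthy, disease
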