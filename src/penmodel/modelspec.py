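"""The four model presets and assembly of the sampling system.

Model 1: 305-d milk = AFC + HYS + animal + e
Model 2: daily milk = AFC + DIM + HYS + animal + pe + e
Model 3: daily milk = AFC + DIM + HPM + animal + pe + e
Model 4: daily milk = AFC + DIM + HYS(fixed) + HPM(random) + animal + pe + e

For models 1-3 the contemporary group may be fitted fixed or random; model 4
fixes HYS and takes HPM random by definition. The assembled system carries
record-level incidence codes per effect, corner-point constraints for fixed
factors beyond the first, and the sparse A-inverse for the additive effect.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .edits import PreparedDataset
from .pedigree import PedigreeTable, RelationshipFactors


@dataclass(frozen=True)
class ModelSpec:
    """Phenotype and effect structure of one of the four preset models."""

    model_id: int
    phenotype: str  # "daily" | "y305"
    fixed: tuple[str, ...]  # ordered subset of ("AFC", "DIM", "HYS")
    random_env: tuple[str, ...]  # subset of ("HYS", "HPM")
    includes_pe: bool
    includes_additive: bool = True

    def __post_init__(self) -> None:
        dup = set(self.fixed) & set(self.random_env)
        if dup:
            raise ValueError(f"factors both fixed and random: {sorted(dup)}")
        if self.phenotype not in ("daily", "y305"):
            raise ValueError(f"unknown phenotype {self.phenotype!r}")

    @property
    def variance_names(self) -> tuple[str, ...]:
        """Variance parameters implied by the spec, residual last."""
        names = [f"sigma2_{f.lower()}" for f in self.random_env]
        names.append("sigma2_a")
        if self.includes_pe:
            names.append("sigma2_pe")
        names.append("sigma2_e")
        return tuple(names)

    def describe(self) -> str:
        terms = list(self.fixed)
        terms += [f"{f}(random)" for f in self.random_env]
        terms.append("animal")
        if self.includes_pe:
            terms.append("pe")
        terms.append("e")
        pheno = "daily milk (kg)" if self.phenotype == "daily" else "305-d milk (kg)"
        return f"model {self.model_id}: {pheno} = " + " + ".join(terms)


def preset(model_id: int, cg_mode: str = "fixed", pe: bool | None = None) -> ModelSpec:
    """One of the four preset models with the contemporary group fixed or random.

    ``cg_mode`` applies to models 1-3; model 4 ignores it (HYS fixed + HPM
    random by definition). ``pe`` overrides the preset's permanent-environment
    flag; requesting pe for model 1 is an error (one record per cow).
    """
    if cg_mode not in ("fixed", "random"):
        raise ValueError(f"cg_mode must be 'fixed' or 'random', got {cg_mode!r}")
    if model_id == 1 and pe:
        raise ValueError("model 1 has a single record per cow: pe is not estimable")
    random_cg = cg_mode == "random"
    if model_id == 1:
        spec = ModelSpec(
            1,
            "y305",
            ("AFC",) if random_cg else ("AFC", "HYS"),
            ("HYS",) if random_cg else (),
            includes_pe=False,
        )
    elif model_id == 2:
        spec = ModelSpec(
            2,
            "daily",
            ("AFC", "DIM") if random_cg else ("AFC", "DIM", "HYS"),
            ("HYS",) if random_cg else (),
            includes_pe=True,
        )
    elif model_id == 3:
        spec = ModelSpec(
            3,
            "daily",
            ("AFC", "DIM") if random_cg else ("AFC", "DIM", "HPM"),
            ("HPM",) if random_cg else (),
            includes_pe=True,
        )
    elif model_id == 4:
        spec = ModelSpec(4, "daily", ("AFC", "DIM", "HYS"), ("HPM",), includes_pe=True)
    else:
        raise ValueError(f"model_id must be 1..4, got {model_id}")
    if pe is not None and pe != spec.includes_pe:
        spec = replace(spec, includes_pe=bool(pe))
    return spec


@dataclass
class EffectBlock:
    """One effect in the assembled system.

    ``kind`` is ``"fixed"``, ``"iid"`` (random with iid levels, incl. pe) or
    ``"additive"`` (pedigree-structured). ``codes`` maps each record to a
    dense level index; ``constrained`` is the corner-point level fixed at 0
    (-1 if none); ``var_name`` names the variance parameter, None for fixed.
    """

    name: str
    kind: str
    codes: np.ndarray
    n_levels: int
    constrained: int = -1
    var_name: str | None = None


@dataclass
class AssembledSystem:
    """Everything the sampler needs: phenotypes, incidence, variance registry."""

    spec: ModelSpec
    y: np.ndarray
    effects: list[EffectBlock]
    variance_names: tuple[str, ...]  # residual ('sigma2_e') last
    ainv: "object"  # scipy.sparse.csr_matrix over pedigree animals
    pedigree: PedigreeTable
    cow_ids: list
    cow_to_animal: np.ndarray  # phenotyped-cow index -> pedigree index

    @property
    def n_records(self) -> int:
        return len(self.y)

    def effect(self, name: str) -> EffectBlock:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)


def assemble(
    spec: ModelSpec, data: PreparedDataset, relfac: RelationshipFactors, ped: PedigreeTable
) -> AssembledSystem:
    """Build the incidence structure for ``spec`` on prepared data.

    Every pedigree animal receives an additive-effect slot whether or not it
    has records (parents are sampled too, which is what makes sire PTA
    available). The first fixed factor absorbs the intercept (no constraint);
    later fixed factors get a corner-point constraint on their first level.
    """
    if spec.phenotype != data.phenotype:
        raise ValueError(
            f"spec expects {spec.phenotype!r} data, prepared data is {data.phenotype!r}"
        )
    try:
        cow_to_animal = ped.indices_of(data.cow_ids)
    except KeyError as err:
        raise ValueError(f"phenotyped cows missing from pedigree: {err}") from err

    effects: list[EffectBlock] = []
    for k, name in enumerate(spec.fixed):
        codes = data.factor_codes(name)
        effects.append(
            EffectBlock(
                name=name,
                kind="fixed",
                codes=codes,
                n_levels=len(data.levels[name]),
                constrained=-1 if k == 0 else 0,
            )
        )
    for name in spec.random_env:
        codes = data.factor_codes(name)
        effects.append(
            EffectBlock(
                name=name,
                kind="iid",
                codes=codes,
                n_levels=len(data.levels[name]),
                var_name=f"sigma2_{name.lower()}",
            )
        )
    effects.append(
        EffectBlock(
            name="animal",
            kind="additive",
            codes=cow_to_animal[data.cow].astype(np.int64),
            n_levels=ped.n_animals,
            var_name="sigma2_a",
        )
    )
    if spec.includes_pe:
        effects.append(
            EffectBlock(
                name="pe",
                kind="iid",
                codes=data.cow.astype(np.int64),
                n_levels=len(data.cow_ids),
                var_name="sigma2_pe",
            )
        )
    return AssembledSystem(
        spec=spec,
        y=np.asarray(data.y, dtype=float),
        effects=effects,
        variance_names=spec.variance_names,
        ainv=relfac.A_inverse,
        pedigree=ped,
        cow_ids=list(data.cow_ids),
        cow_to_animal=cow_to_animal,
    )
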