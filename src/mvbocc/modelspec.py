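"""Candidate-model specifications.

A :class:`ModelSpec` names which terms are active in one candidate model:

* per-species occurrence covariates (first-order natural parameters ``f_i``),
* which species pairs get a pairwise natural parameter ``f_ij`` and over
  which covariates,
* per-species detection (intensity-of-use) covariates,
* which detection *modifiers* are active -- ``(focal, conditioning)`` entries
  that shift the focal species' detection logit when the conditioning
  species is latently present.

The term name ``"const"`` denotes the intercept; all other terms must be
columns of the site-covariate table.  Specs round-trip through YAML so that
a candidate set can be declared in configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

PAIR_SEP = "~"

__all__ = ["ModelSpec", "PAIR_SEP"]


@dataclass
class ModelSpec:
    species: tuple[str, ...]
    occurrence: dict[str, tuple[str, ...]]
    detection: dict[str, tuple[str, ...]]
    pairs: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)
    modifiers: tuple[tuple[str, str], ...] = ()
    name: str = ""

    def __post_init__(self):
        self.species = tuple(str(s) for s in self.species)
        order = {sp: k for k, sp in enumerate(self.species)}
        if len(order) != len(self.species):
            raise ValueError("duplicate species names")
        for sp in self.species:
            if sp not in self.occurrence:
                raise ValueError(f"no occurrence terms for species {sp!r}")
            if sp not in self.detection:
                raise ValueError(f"no detection terms for species {sp!r}")
        self.occurrence = {sp: tuple(self.occurrence[sp]) for sp in self.species}
        self.detection = {sp: tuple(self.detection[sp]) for sp in self.species}
        canon: dict[tuple[str, str], tuple[str, ...]] = {}
        for (a, b), terms in self.pairs.items():
            if a not in order or b not in order:
                raise ValueError(f"pair ({a!r}, {b!r}) names unknown species")
            if a == b:
                raise ValueError(f"pair ({a!r}, {b!r}) must be two distinct species")
            key = (a, b) if order[a] < order[b] else (b, a)
            if key in canon:
                raise ValueError(f"duplicate pair {key}")
            canon[key] = tuple(terms)
        self.pairs = dict(sorted(canon.items(), key=lambda kv: (order[kv[0][0]], order[kv[0][1]])))
        mods = []
        for focal, cond in self.modifiers:
            if focal not in order or cond not in order:
                raise ValueError(f"modifier ({focal!r}, {cond!r}) names unknown species")
            if focal == cond:
                raise ValueError("a species cannot modify its own detection")
            if (focal, cond) not in mods:
                mods.append((focal, cond))
        self.modifiers = tuple(mods)

    # -- parameter layout ---------------------------------------------------

    @property
    def param_names(self) -> list[str]:
        """Flat, ordered parameter names: occurrence blocks per species, then
        pairwise blocks, detection blocks, then modifiers."""
        names = []
        for sp in self.species:
            names += [f"psi[{sp}]:{t}" for t in self.occurrence[sp]]
        for (a, b), terms in self.pairs.items():
            names += [f"psi[{a}{PAIR_SEP}{b}]:{t}" for t in terms]
        for sp in self.species:
            names += [f"p[{sp}]:{t}" for t in self.detection[sp]]
        names += [f"p[{focal}]|{cond}" for focal, cond in self.modifiers]
        return names

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def covariate_terms(self) -> set[str]:
        terms: set[str] = set()
        for block in (self.occurrence, self.detection):
            for t in block.values():
                terms |= set(t)
        for t in self.pairs.values():
            terms |= set(t)
        terms.discard("const")
        return terms

    def validate_covariates(self, columns: Sequence[str]) -> None:
        missing = self.covariate_terms() - set(columns)
        if missing:
            raise ValueError(
                f"model {self.name or '<unnamed>'} references covariates absent "
                f"from the site table: {sorted(missing)}"
            )

    def key(self) -> tuple:
        """Hashable structural identity (name excluded) for deduplication."""
        return (
            self.species,
            tuple(self.occurrence.items()),
            tuple(self.detection.items()),
            tuple(self.pairs.items()),
            self.modifiers,
        )

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "species": list(self.species),
            "occurrence": {sp: list(t) for sp, t in self.occurrence.items()},
            "detection": {sp: list(t) for sp, t in self.detection.items()},
            "pairs": {f"{a}{PAIR_SEP}{b}": list(t) for (a, b), t in self.pairs.items()},
            "modifiers": [list(m) for m in self.modifiers],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        pairs = {}
        for key, terms in (d.get("pairs") or {}).items():
            a, _, b = key.partition(PAIR_SEP)
            if not b:
                raise ValueError(f"pair key {key!r} must be '<a>{PAIR_SEP}<b>'")
            pairs[(a, b)] = tuple(terms)
        return cls(
            species=tuple(d["species"]),
            occurrence={sp: tuple(t) for sp, t in d["occurrence"].items()},
            detection={sp: tuple(t) for sp, t in d["detection"].items()},
            pairs=pairs,
            modifiers=tuple((m[0], m[1]) for m in d.get("modifiers") or []),
            name=str(d.get("name", "")),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
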