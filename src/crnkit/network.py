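"""Reaction-network container with deduplication and text serialization."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .chemgraph import Species, species_from_smiles
from .sampler import Reaction


@dataclass
class ReactionNetwork:
    """Ordered unique species and reactions, with per-reaction provenance.

    Reactions are deduplicated under their direction-specific canonical
    multiset keys; adding an existing reaction is a no-op, so growth is
    monotone and idempotent.
    """

    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    provenance: dict[tuple, dict] = field(default_factory=dict)
    _species_ids: set[str] = field(default_factory=set, repr=False)
    _reaction_keys: set[tuple] = field(default_factory=set, repr=False)

    def __post_init__(self) -> None:
        self._species_ids = {s.canonical_id for s in self.species}
        self._reaction_keys = {r.key for r in self.reactions}

    def add_species(self, sp: Species) -> bool:
        if sp.canonical_id in self._species_ids:
            return False
        self.species.append(sp)
        self._species_ids.add(sp.canonical_id)
        return True

    def add_reaction(self, rxn: Reaction, **tags) -> bool:
        """Add a reaction (and its species); returns True if it was new."""
        if rxn.key in self._reaction_keys:
            return False
        for sp in list(rxn.reactants) + list(rxn.products):
            self.add_species(sp)
        self.reactions.append(rxn)
        self._reaction_keys.add(rxn.key)
        self.provenance[rxn.key] = dict(tags)
        return True

    def has_reaction(self, rxn: Reaction) -> bool:
        return rxn.key in self._reaction_keys

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self) -> dict[str, int]:
        return {s.canonical_id: i for i, s in enumerate(self.species)}

    def copy(self) -> "ReactionNetwork":
        net = ReactionNetwork(
            species=list(self.species),
            reactions=list(self.reactions),
            provenance={k: dict(v) for k, v in self.provenance.items()},
        )
        return net

    def signature(self) -> tuple:
        """Order-independent identity of the network contents."""
        return (
            tuple(sorted(self._species_ids)),
            tuple(sorted(self._reaction_keys)),
        )

    # -- serialization ------------------------------------------------------

    def dumps(self) -> str:
        lines = ["# crnkit reaction network", "[species]"]
        lines.extend(s.canonical_id for s in self.species)
        lines.append("[reactions]")
        for r in self.reactions:
            tags = self.provenance.get(r.key, {})
            tag_str = " ".join(f"{k}={v}" for k, v in sorted(tags.items()))
            lines.append(f"{r.smiles()}\t{tag_str}".rstrip())
        return "\n".join(lines) + "\n"

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(self.dumps())

    @classmethod
    def loads(cls, text: str) -> "ReactionNetwork":
        from collections import Counter

        net = cls()
        section = None
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line in ("[species]", "[reactions]"):
                section = line
                continue
            if section == "[species]":
                net.add_species(species_from_smiles(line))
            elif section == "[reactions]":
                parts = line.split("\t")
                rsmi = parts[0]
                tags = {}
                if len(parts) > 1 and parts[1]:
                    for kv in parts[1].split():
                        k, v = kv.split("=", 1)
                        tags[k] = v
                lhs, rhs = rsmi.split(">>")
                reactants = Counter(species_from_smiles(s) for s in lhs.split("."))
                products = Counter(species_from_smiles(s) for s in rhs.split("."))
                net.add_reaction(Reaction(reactants, products), **tags)
        return net

    @classmethod
    def load(cls, path: str | Path) -> "ReactionNetwork":
        return cls.loads(Path(path).read_text())
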