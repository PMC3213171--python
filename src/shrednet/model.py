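"""Stoichiometric model container and model-variant constructors.

A biochemical model is held as a species × reactions stoichiometric matrix
``S`` (negative coefficients = consumed, positive = produced), a parallel
regulatory matrix ``R`` of allosteric effects (−1 inhibition, +1 activation,
0 none), per-reaction reversibility flags, and an optional map of reactions
to canonical pathway groups.  Both matrices are stored species × reactions;
readers accept the transposed orientation via a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StoichiometricModel",
    "ModelError",
    "remove_species",
    "strip_regulation",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_reversibility_tsv",
    "write_reversibility_tsv",
    "read_groups_tsv",
    "write_groups_tsv",
    "read_model_tsv",
    "write_model_tsv",
]


class ModelError(ValueError):
    """Structural problem in a stoichiometric/regulatory model."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ModelError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class StoichiometricModel:
    """Immutable species-level model.

    Parameters
    ----------
    species_ids, reaction_ids
        Unique identifiers naming the rows and columns of ``S`` and ``R``.
    S
        Signed stoichiometric coefficients, species × reactions.
    reversible
        Per-reaction reversibility flags.
    R
        Regulatory matrix, species × reactions, entries in {−1, 0, +1}.
        Defaults to all zeros (no allosteric regulation).
    groups
        Optional map reaction id → canonical group label.
    """

    species_ids: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    S: np.ndarray
    reversible: tuple[bool, ...]
    R: np.ndarray = field(default=None)  # type: ignore[assignment]
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "species_ids", tuple(self.species_ids))
        object.__setattr__(self, "reaction_ids", tuple(self.reaction_ids))
        object.__setattr__(self, "reversible", tuple(bool(b) for b in self.reversible))
        S = np.asarray(self.S, dtype=float)
        object.__setattr__(self, "S", S)
        ns, nr = len(self.species_ids), len(self.reaction_ids)
        _check_unique(self.species_ids, "species")
        _check_unique(self.reaction_ids, "reaction")
        if S.shape != (ns, nr):
            raise ModelError(
                f"S has shape {S.shape}, expected ({ns} species, {nr} reactions)"
            )
        if self.R is None:
            R = np.zeros((ns, nr))
        else:
            R = np.asarray(self.R, dtype=float)
        object.__setattr__(self, "R", R)
        if R.shape != (ns, nr):
            raise ModelError(
                f"R has shape {R.shape}, expected ({ns} species, {nr} reactions)"
            )
        if not np.isin(R, (-1.0, 0.0, 1.0)).all():
            bad = sorted(set(R.ravel()) - {-1.0, 0.0, 1.0})
            raise ModelError(f"R entries must be -1, 0 or +1; found {bad}")
        if len(self.reversible) != nr:
            raise ModelError(
                f"{len(self.reversible)} reversibility flags for {nr} reactions"
            )
        if self.groups is not None:
            unknown = set(self.groups) - set(self.reaction_ids)
            if unknown:
                raise ModelError(f"groups reference unknown reactions: {sorted(unknown)}")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def species_index(self, species: str) -> int:
        try:
            return self.species_ids.index(species)
        except ValueError:
            raise ModelError(f"unknown species identifier: {species!r}") from None


def remove_species(model: StoichiometricModel, species: Iterable[str]) -> StoichiometricModel:
    """Delete species rows from both S and R; the reaction set is unchanged.

    Used to build "no cofactors" model variants by deleting currency
    metabolites such as ATP, NADH and NADPH, which removes every edge those
    species mediate (stoichiometric and regulatory alike).
    """
    drop = set(species)
    if not drop:
        return model
    idx = sorted(model.species_index(s) for s in drop)
    keep = [i for i in range(model.n_species) if i not in set(idx)]
    return replace(
        model,
        species_ids=tuple(model.species_ids[i] for i in keep),
        S=model.S[keep, :],
        R=model.R[keep, :],
    )


def strip_regulation(model: StoichiometricModel) -> StoichiometricModel:
    """Zero out the regulatory matrix, leaving stoichiometry untouched."""
    return replace(model, R=np.zeros_like(model.R))


# ---------------------------------------------------------------------------
# Delimited-text IO.  Matrix files are TSV with a header row of reaction ids
# and a first column of species ids; reversibility and group files are
# two-column TSVs.


def read_matrix_tsv(path: str | Path, *, transpose: bool = False) -> pd.DataFrame:
    """Read a species × reactions matrix (set ``transpose`` if the file is
    reactions × species, e.g. a regulatory table written with effectors as
    columns)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ModelError(f"duplicate column identifiers in {path}: {dupes}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if transpose:
        df = df.T
    return df


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_reversibility_tsv(path: str | Path) -> dict[str, bool]:
    df = pd.read_csv(path, sep="\t", header=None, names=["reaction", "reversible"])
    out: dict[str, bool] = {}
    for rid, flag in zip(df["reaction"].astype(str), df["reversible"]):
        text = str(flag).strip().lower()
        if text in {"1", "true", "yes"}:
            out[rid] = True
        elif text in {"0", "false", "no"}:
            out[rid] = False
        else:
            raise ModelError(f"unparseable reversibility flag {flag!r} for {rid!r}")
    return out


def write_reversibility_tsv(model: StoichiometricModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, rev in zip(model.reaction_ids, model.reversible):
            fh.write(f"{rid}\t{int(rev)}\n")


def read_groups_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["reaction", "group"])
    return dict(zip(df["reaction"].astype(str), df["group"].astype(str)))


def write_groups_tsv(groups: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, grp in groups.items():
            fh.write(f"{rid}\t{grp}\n")


def read_model_tsv(
    stoich_path: str | Path,
    *,
    regulation_path: str | Path | None = None,
    reversible_path: str | Path | None = None,
    groups_path: str | Path | None = None,
    transpose_regulation: bool = False,
) -> StoichiometricModel:
    """Assemble a model from the delimited-text file set.

    Reactions missing from the reversibility file default to irreversible;
    a regulation file may name a subset of the species (unlisted rows are
    zero) but must not name unknown species or reactions.
    """
    sdf = read_matrix_tsv(stoich_path)
    species = tuple(sdf.index)
    reactions = tuple(sdf.columns)

    R = np.zeros(sdf.shape)
    if regulation_path is not None:
        rdf = read_matrix_tsv(regulation_path, transpose=transpose_regulation)
        unknown_sp = set(rdf.index) - set(species)
        if unknown_sp:
            raise ModelError(f"regulation names unknown species: {sorted(unknown_sp)}")
        unknown_rx = set(rdf.columns) - set(reactions)
        if unknown_rx:
            raise ModelError(f"regulation names unknown reactions: {sorted(unknown_rx)}")
        rdf = rdf.reindex(index=list(species), columns=list(reactions), fill_value=0.0)
        R = rdf.to_numpy(dtype=float)

    reversible = [False] * len(reactions)
    if reversible_path is not None:
        flags = read_reversibility_tsv(reversible_path)
        unknown = set(flags) - set(reactions)
        if unknown:
            raise ModelError(f"reversibility names unknown reactions: {sorted(unknown)}")
        reversible = [flags.get(r, False) for r in reactions]

    groups = read_groups_tsv(groups_path) if groups_path is not None else None
    return StoichiometricModel(
        species_ids=species,
        reaction_ids=reactions,
        S=sdf.to_numpy(dtype=float),
        reversible=tuple(reversible),
        R=R,
        groups=groups,
    )


def write_model_tsv(model: StoichiometricModel, directory: str | Path) -> dict[str, Path]:
    """Write the full file set (stoichiometry, regulation, reversibility and,
    if present, groups) into ``directory``; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "stoich": directory / "stoichiometry.tsv",
        "regulation": directory / "regulation.tsv",
        "reversible": directory / "reversible.tsv",
    }
    idx = list(model.species_ids)
    cols = list(model.reaction_ids)
    write_matrix_tsv(pd.DataFrame(model.S, index=idx, columns=cols), paths["stoich"])
    write_matrix_tsv(pd.DataFrame(model.R, index=idx, columns=cols), paths["regulation"])
    write_reversibility_tsv(model, paths["reversible"])
    if model.groups is not None:
        paths["groups"] = directory / "groups.tsv"
        write_groups_tsv(model.groups, paths["groups"])
    return paths
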