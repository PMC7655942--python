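"""Shorthand lipid nomenclature and the species -> class taxonomy.

Plasma lipidomic panels report species in the Lipid Maps / Liebisch
shorthand, e.g. ``PC(P-17:0/20:4) (a)`` (an alkenyl-ether, "plasmalogen",
phosphatidylcholine with a 17:0 alkenyl and a 20:4 acyl chain, first of two
chromatographically separated but otherwise unresolved isomers) or
``SM(d18:1/24:1)`` (a sphingomyelin with a d18:1 sphingoid base and a 24:1
n-acyl chain).  This module parses that grammar into structured records,
keeps the species -> class registry, and aggregates concentrations to class
totals by summation on the raw concentration scale.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Chain",
    "LipidSpecies",
    "PanelRegistry",
    "MalformedLipidName",
    "parse_lipid_name",
    "class_totals",
    "read_registry",
    "write_registry",
    "DEFAULT_BASE_CLASSES",
]


class MalformedLipidName(ValueError):
    """Raised when a lipid name does not follow the shorthand grammar."""


#: Base class codes recognised out of the box.  Ether subclasses (e.g.
#: ``PC(O)``, ``PC(P)``, ``TG(O)``) are derived from the O-/P- chain prefix
#: and do not appear here.  A registry file may extend this vocabulary.
DEFAULT_BASE_CLASSES = frozenset(
    {
        "PC", "PE", "PS", "PI", "PG",
        "LPC", "LPE", "LPI",
        "SM", "Cer", "dhCer", "HexCer", "Hex2Cer", "Hex3Cer",
        "GM1", "GM3", "GD3", "sulfatide",
        "TG", "DG", "MG",
        "CE", "DE", "COH",
        "AC", "FFA",
    }
)

# Branch tags map to the carbon:double-bond content of the branched chain.
# MHDA = methylhexadecanoic acid, i.e. a methyl-branched 16:0.
_BRANCH_CONTENT = {"MHDA": (16, 0)}

_CHAIN_RE = re.compile(r"^(d|t)?(\d+):(\d+)$")
_BRANCH_RE = re.compile(r"^(\d+)-([A-Za-z]+)$")
_TAIL_RE = re.compile(r"\s*(\((a|b)\)|\[(sn\d)\]|\[NL-([^\]]+)\])")

# How many chains a fully specified species of each base class carries.
_EXPECTED_CHAINS = {
    "TG": 3,
    "DG": 2, "PC": 2, "PE": 2, "PS": 2, "PI": 2, "PG": 2,
    "SM": 2, "Cer": 2, "dhCer": 2, "HexCer": 2, "Hex2Cer": 2,
    "Hex3Cer": 2, "GM1": 2, "GM3": 2, "GD3": 2, "sulfatide": 2,
    "LPC": 1, "LPE": 1, "LPI": 1, "CE": 1, "DE": 1, "AC": 1,
    "FFA": 1, "MG": 1, "COH": 0,
}


@dataclass(frozen=True)
class Chain:
    """One fatty chain (or sum-composition) descriptor."""

    carbons: int
    double_bonds: int
    ether: str | None = None  # "O" (alkyl) or "P" (alkenyl/plasmalogen)
    sphingoid: str | None = None  # "d" or "t" hydroxylation prefix
    branch: str | None = None  # e.g. "15-MHDA"

    def serialise(self) -> str:
        if self.branch is not None:
            return self.branch
        prefix = f"{self.ether}-" if self.ether else ""
        base = self.sphingoid or ""
        return f"{prefix}{base}{self.carbons}:{self.double_bonds}"


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed shorthand lipid name.

    ``chains`` is empty when only the sum composition is known (e.g.
    ``SM(43:1)``); ``total_carbons``/``total_double_bonds`` are always
    populated.  Plasmalogen (P-) chains contribute their printed double
    bonds only; the vinyl-ether bond is not counted.
    """

    raw_name: str
    class_code: str
    total_carbons: int
    total_double_bonds: int
    chains: tuple[Chain, ...] = ()
    separators: tuple[str, ...] = ()
    isomer_label: str | None = None  # "a" or "b"
    sn_tag: str | None = None  # e.g. "sn1"
    neutral_loss_tag: Chain | None = None  # from "[NL-16:0]"

    @property
    def base_class(self) -> str:
        """Class code without the ether-subclass parenthetical."""
        return self.class_code.split("(")[0]

    def serialise(self) -> str:
        """Canonical shorthand form; the inverse of :func:`parse_lipid_name`."""
        if self.chains:
            parts = [self.chains[0].serialise()]
            for sep, ch in zip(self.separators, self.chains[1:]):
                parts.append(sep + ch.serialise())
            body = "".join(parts)
        else:
            prefix = ""
            if self.class_code.endswith("(O)"):
                prefix = "O-"
            elif self.class_code.endswith("(P)"):
                prefix = "P-"
            body = f"{prefix}{self.total_carbons}:{self.total_double_bonds}"
        name = f"{self.base_class}({body})"
        if self.sn_tag:
            name += f" [{self.sn_tag}]"
        if self.neutral_loss_tag:
            name += f" [NL-{self.neutral_loss_tag.serialise()}]"
        if self.isomer_label:
            name += f" ({self.isomer_label})"
        return name


def _parse_chain(token: str, name: str) -> Chain:
    token = token.strip()
    ether = None
    if token.startswith("O-") or token.startswith("P-"):
        ether, token = token[0], token[2:]
    m = _CHAIN_RE.match(token)
    if m:
        return Chain(
            carbons=int(m.group(2)),
            double_bonds=int(m.group(3)),
            ether=ether,
            sphingoid=m.group(1),
        )
    b = _BRANCH_RE.match(token)
    if b and b.group(2) in _BRANCH_CONTENT:
        carbons, dbs = _BRANCH_CONTENT[b.group(2)]
        return Chain(carbons=carbons, double_bonds=dbs, ether=ether, branch=token)
    raise MalformedLipidName(
        f"{name!r}: chain token {token!r} is not of the form [d|t]C:D, "
        f"O-C:D, P-C:D or a known branch tag"
    )


def parse_lipid_name(
    name: str, known_classes: Iterable[str] = DEFAULT_BASE_CLASSES
) -> LipidSpecies:
    """Parse a shorthand lipid name into a :class:`LipidSpecies`.

    The grammar is ``CLASS(prefix-chain[/chain][_chain]) [tags]``:
    ``O-``/``P-`` prefixes on the first chain mark alkyl/alkenyl ether
    species and move the class to the corresponding subclass (``PC(O)``,
    ``PC(P)``); a leading ``d`` (or ``t``) on a chain marks the sphingoid
    base; ``/`` separates chains of known sn position and ``_`` chains of
    unknown position; trailing ``(a)``/``(b)`` label chromatographically
    separated but unresolved isomers; ``[sn1]`` records the acyl position
    of a lyso species; ``[NL-16:0]`` records the neutral-loss fragment
    identifying the measured TG species.
    """
    if not name or not name.strip():
        raise MalformedLipidName("empty lipid name")
    s = name.strip()
    if s.count("(") != s.count(")"):
        raise MalformedLipidName(f"{name!r}: unbalanced parentheses")

    open_idx = s.find("(")
    if open_idx <= 0:
        raise MalformedLipidName(f"{name!r}: expected CLASS(...) structure")
    base = s[:open_idx]
    known = set(known_classes)
    if base not in known:
        raise MalformedLipidName(f"{name!r}: unknown class code {base!r}")

    depth, close_idx = 0, -1
    for i, c in enumerate(s[open_idx:], start=open_idx):
        if c == "(":
            depth += 1
        elif c == ")":
            depth -= 1
            if depth == 0:
                close_idx = i
                break
    body = s[open_idx + 1 : close_idx]
    tail = s[close_idx + 1 :]

    isomer = sn_tag = None
    nl_tag: Chain | None = None
    pos = 0
    while pos < len(tail):
        m = _TAIL_RE.match(tail, pos)
        if not m:
            raise MalformedLipidName(f"{name!r}: unrecognised suffix {tail[pos:]!r}")
        if m.group(2):
            isomer = m.group(2)
        elif m.group(3):
            sn_tag = m.group(3)
        else:
            nl_tag = _parse_chain(m.group(4), name)
        pos = m.end()

    tokens = re.split(r"([/_])", body)
    chain_tokens = tokens[0::2]
    separators = tuple(tokens[1::2])
    chains = tuple(_parse_chain(t, name) for t in chain_tokens)

    class_code = base
    if chains and chains[0].ether:
        class_code = f"{base}({chains[0].ether})"

    expected = _EXPECTED_CHAINS.get(base, 2)
    fully_specified = len(chains) >= expected and expected > 0
    if fully_specified:
        total_c = sum(c.carbons for c in chains)
        total_d = sum(c.double_bonds for c in chains)
    elif len(chains) == 1:
        # a single token below the expected chain count is a sum composition
        total_c, total_d = chains[0].carbons, chains[0].double_bonds
        chains, separators = (), ()
    else:
        raise MalformedLipidName(
            f"{name!r}: {len(chains)} chains given, expected 1 or {expected}"
        )

    return LipidSpecies(
        raw_name=s,
        class_code=class_code,
        total_carbons=total_c,
        total_double_bonds=total_d,
        chains=chains,
        separators=separators,
        isomer_label=isomer,
        sn_tag=sn_tag,
        neutral_loss_tag=nl_tag,
    )


@dataclass
class PanelRegistry:
    """The measured species panel and its species -> class taxonomy."""

    species: list[LipidSpecies] = field(default_factory=list)

    @property
    def class_of(self) -> dict[str, str]:
        return {sp.raw_name: sp.class_code for sp in self.species}

    @property
    def classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for sp in self.species:
            seen.setdefault(sp.class_code)
        return list(seen)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @classmethod
    def from_names(
        cls, names: Sequence[str], known_classes: Iterable[str] = DEFAULT_BASE_CLASSES
    ) -> "PanelRegistry":
        return cls(species=[parse_lipid_name(n, known_classes) for n in names])

    @classmethod
    def from_mapping(cls, class_of: Mapping[str, str]) -> "PanelRegistry":
        """Build from an explicit species -> class mapping (registry file).

        Class codes in the mapping override the parser's derivation, and the
        mapping's base codes extend the default class vocabulary.
        """
        extra = {c.split("(")[0] for c in class_of.values()}
        known = DEFAULT_BASE_CLASSES | extra
        species = []
        for name, code in class_of.items():
            sp = parse_lipid_name(name, known)
            if sp.class_code != code:
                sp = LipidSpecies(**{**sp.__dict__, "class_code": code})
            species.append(sp)
        return cls(species=species)


def read_registry(path: str | Path) -> PanelRegistry:
    """Read a two-column (species_name, class_code) delimited registry file."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"registry file {path} must have two columns (got {df.shape[1]})")
    name_col, class_col = df.columns[:2]
    return PanelRegistry.from_mapping(dict(zip(df[name_col], df[class_col])))


def write_registry(registry: PanelRegistry, path: str | Path) -> None:
    pd.DataFrame(
        {"species_name": [sp.raw_name for sp in registry.species],
         "class_code": [sp.class_code for sp in registry.species]}
    ).to_csv(path, index=False)


def class_totals(concentrations: pd.DataFrame, registry: PanelRegistry) -> pd.DataFrame:
    """Sum species concentrations to class totals on the raw scale.

    Parameters
    ----------
    concentrations
        sample x species table of (untransformed) concentrations; every
        column must appear in the registry.
    registry
        the species -> class taxonomy.

    Returns
    -------
    sample x class table, one column per distinct class present.
    """
    mapping = registry.class_of
    unknown = [c for c in concentrations.columns if c not in mapping]
    if unknown:
        raise KeyError(f"species not in registry: {unknown}")
    groups = pd.Index([mapping[c] for c in concentrations.columns], name="class")
    totals = concentrations.T.groupby(groups, sort=False).sum().T
    return totals
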