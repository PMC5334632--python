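"""3-alkyl pyridine alkaloid (3-APA) compound library.

Builds the thirteen curated reference compounds (cyclostellettamines,
haliclamines, viscosamine, viscosalines) and combinatorially expands
homolog series from class-specific formula rules, so that unknown chain
lengths can be dereplicated by exact mass.

Class rules (n, m, ... are alkyl chain carbon counts):

===============  ========================  ===========================
class            intact species            formula rule
===============  ========================  ===========================
cyclostellettamine  cyclic dimer, 2+ cation   C(10+n+m) H(2(n+m)+8) N2
haliclamine         cyclic dimer, neutral     C(10+n+m) H(2(n+m)+14) N2
viscosamine         cyclic trimer, 3+ cation  C(15+S) H(2S+12) N3
viscosaline         linear, 1+ cation         C(13+n+m) H(2(n+m)+14) N3 O2
===============  ========================  ===========================

Onium cleavage of an N-alkyl pyridinium bond yields the class-specific
F1/F2 fragments: C(5+k)H(2k+4)N+ for a pyridinium (Pyr) ring carrying a
k-carbon chain, C(5+k)H(2k+8)N+ for a tetrahydropyridine (THP) ring.
The moiety-level diagnostic fragments are C6H12N+ (m/z 98.0970, THP)
and C7H8N+ (m/z 106.0657, Pyr).

Several printed reference m/z values are internally inconsistent with
their own printed formulas (they appear to be measured rather than
calculated values).  Each entry therefore stores printed values, where
available, alongside recomputed ones; matching uses the recomputed,
self-consistent values by default with a switch to match against the
printed ones instead.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .formula import (
    ElementalFormula,
    IonSpecies,
    add_protons,
    ion_mz,
    parse_formula,
)

__all__ = [
    "ApaClass",
    "Moiety",
    "FragmentIon",
    "ApaCompound",
    "MassLibrary",
    "LibraryHit",
    "make_cyclostellettamine",
    "make_haliclamine",
    "make_viscosamine",
    "make_viscosaline",
    "curated_library",
    "expand_homologs",
    "diagnostic_fragments",
    "PYR_DIAGNOSTIC",
    "THP_DIAGNOSTIC",
]

ApaClass = Literal["cyclostellettamine", "haliclamine", "viscosamine", "viscosaline"]
Moiety = Literal["Pyr", "THP"]

#: Default chain-length expansion range, covering all curated species.
DEFAULT_CHAIN_RANGE = (8, 14)


@dataclass(frozen=True)
class FragmentIon:
    """A predicted fragment ion of a compound.

    ``mz`` is always recomputed from ``formula``/``charge``; the printed
    reference value, when one exists and differs, is in ``mz_printed``.
    """

    role: Literal["diagnostic", "F1", "F2", "secondary"]
    formula: ElementalFormula
    charge: int
    parent_moiety: Moiety | None = None
    mz_printed: float | None = None
    mz: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mz", ion_mz(self.formula, self.charge))


THP_DIAGNOSTIC = FragmentIon("diagnostic", parse_formula("C6H12N"), 1, "THP")
PYR_DIAGNOSTIC = FragmentIon("diagnostic", parse_formula("C7H8N"), 1, "Pyr")


def diagnostic_fragments() -> list[FragmentIon]:
    """The two moiety-level diagnostic fragment ions (THP then Pyr)."""
    return [THP_DIAGNOSTIC, PYR_DIAGNOSTIC]


@dataclass
class ApaCompound:
    """One 3-APA entry: formula rules, ion species and predicted fragments."""

    name: str
    apa_class: ApaClass
    moieties: dict[str, int]
    topology: Literal["cyclic-dimer", "cyclic-trimer", "linear"]
    chain_lengths: tuple[int, ...]
    base_formula: ElementalFormula
    ion_species: list[IonSpecies]
    predicted_fragments: list[FragmentIon]
    beta_alanine_units: int = 0
    curated: bool = False
    rule_generated: bool = True
    #: printed reference values: ion label -> m/z, plus "formula" and
    #: "fragments" ([(formula string, m/z, charge)]) where available
    printed: dict = field(default_factory=dict)
    #: printed ions whose composition is not derivable from the formula
    printed_only_ions: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_chains = {"cyclic-dimer": 2, "cyclic-trimer": 3, "linear": 2}[self.topology]
        if len(self.chain_lengths) != n_chains:
            raise ValueError(
                f"{self.topology} requires {n_chains} chains, got {self.chain_lengths}"
            )
        if any(n < 1 for n in self.chain_lengths):
            raise ValueError("chain lengths must be >= 1")

    @property
    def fragment_ions(self) -> list[FragmentIon]:
        """F1/F2 fragments only (diagnostics excluded)."""
        return [f for f in self.predicted_fragments if f.role in ("F1", "F2")]

    @property
    def diagnostics(self) -> list[FragmentIon]:
        return [f for f in self.predicted_fragments if f.role == "diagnostic"]


def _pyr_fragment(k: int, printed_mz: float | None = None) -> FragmentIon:
    return FragmentIon(
        "F1", ElementalFormula({"C": 5 + k, "H": 2 * k + 4, "N": 1}), 1, "Pyr", printed_mz
    )


def _thp_fragment(k: int, printed_mz: float | None = None) -> FragmentIon:
    return FragmentIon(
        "F1", ElementalFormula({"C": 5 + k, "H": 2 * k + 8, "N": 1}), 1, "THP", printed_mz
    )


def _order_f1_f2(frags: Sequence[FragmentIon]) -> list[FragmentIon]:
    """F1 = lighter fragment, F2 = heavier; ties keep both as F1/F2."""
    lo, hi = sorted(frags, key=lambda f: f.mz)
    lo = FragmentIon("F1", lo.formula, lo.charge, lo.parent_moiety, lo.mz_printed)
    hi = FragmentIon("F2", hi.formula, hi.charge, hi.parent_moiety, hi.mz_printed)
    return [lo, hi]


def _moiety_diagnostics(moieties: dict[str, int]) -> list[FragmentIon]:
    out = []
    if moieties.get("THP", 0) > 0:
        out.append(THP_DIAGNOSTIC)
    if moieties.get("Pyr", 0) > 0:
        out.append(PYR_DIAGNOSTIC)
    return out


def make_cyclostellettamine(n: int, m: int) -> ApaCompound:
    """Cyclic pyridinium dimer with chains of n and m carbons.

    The intact species is a native dication observed at formula mass / 2;
    the singly charged molecular ion is formula + 1 H.
    """
    total = n + m
    base = ElementalFormula({"C": 10 + total, "H": 2 * total + 8, "N": 2})
    ions = [
        IonSpecies(base, 2, "[M]2+"),
        IonSpecies(add_protons(base, 1), 1, "[M+H]+"),
    ]
    moieties = {"Pyr": 2}
    frags = _order_f1_f2([_pyr_fragment(n), _pyr_fragment(m)])
    return ApaCompound(
        name=f"cyclostellettamine({min(n, m)},{max(n, m)})",
        apa_class="cyclostellettamine",
        moieties=moieties,
        topology="cyclic-dimer",
        chain_lengths=(min(n, m), max(n, m)),
        base_formula=base,
        ion_species=ions,
        predicted_fragments=_moiety_diagnostics(moieties) + frags,
    )


def make_haliclamine(n: int, m: int) -> ApaCompound:
    """Cyclic tetrahydropyridine (THP-THP) dimer, neutral molecule."""
    total = n + m
    base = ElementalFormula({"C": 10 + total, "H": 2 * total + 14, "N": 2})
    ions = [
        IonSpecies(add_protons(base, 1), 1, "[M+H]+"),
        IonSpecies(add_protons(base, 2), 2, "[M+2H]2+"),
    ]
    moieties = {"THP": 2}
    frags = _order_f1_f2([_thp_fragment(n), _thp_fragment(m)])
    return ApaCompound(
        name=f"haliclamine({min(n, m)},{max(n, m)})",
        apa_class="haliclamine",
        moieties=moieties,
        topology="cyclic-dimer",
        chain_lengths=(min(n, m), max(n, m)),
        base_formula=base,
        ion_species=ions,
        predicted_fragments=_moiety_diagnostics(moieties) + frags,
    )


def make_viscosamine(n1: int, n2: int, n3: int) -> ApaCompound:
    """Cyclic pyridinium trimer, native trication at formula mass / 3."""
    total = n1 + n2 + n3
    base = ElementalFormula({"C": 15 + total, "H": 2 * total + 12, "N": 3})
    chains = tuple(sorted((n1, n2, n3)))
    moieties = {"Pyr": 3}
    return ApaCompound(
        name=f"viscosamine{chains}",
        apa_class="viscosamine",
        moieties=moieties,
        topology="cyclic-trimer",
        chain_lengths=chains,
        base_formula=base,
        ion_species=[IonSpecies(base, 3, "[M]3+")],
        predicted_fragments=_moiety_diagnostics(moieties),
    )


def make_viscosaline(n: int, m: int) -> ApaCompound:
    """Linear bis-pyridinium with one beta-alanine unit, native monocation.

    Observed singly charged at formula mass and doubly charged at
    (formula mass + H) / 2.  A second printed doubly charged species is
    not derivable from the formula and is carried only on curated
    entries (``printed_only_ions``).
    """
    total = n + m
    base = ElementalFormula({"C": 13 + total, "H": 2 * total + 14, "N": 3, "O": 2})
    ions = [
        IonSpecies(base, 1, "[M]+"),
        IonSpecies(add_protons(base, 1), 2, "[M+H]2+"),
    ]
    moieties = {"Pyr": 2}
    return ApaCompound(
        name=f"viscosaline({min(n, m)},{max(n, m)})",
        apa_class="viscosaline",
        moieties=moieties,
        topology="linear",
        chain_lengths=(min(n, m), max(n, m)),
        base_formula=base,
        ion_species=ions,
        predicted_fragments=_moiety_diagnostics(moieties),
        beta_alanine_units=1,
    )


_MAKERS = {
    "cyclostellettamine": make_cyclostellettamine,
    "haliclamine": make_haliclamine,
    "viscosamine": make_viscosamine,
    "viscosaline": make_viscosaline,
}


# ---------------------------------------------------------------------------
# Curated reference entries.
#
# Each row: name, class, chains, printed singly-charged-form formula,
# printed [M+H]+-column m/z, printed doubly charged m/z (or trication),
# printed fragments [(formula, m/z, charge)], printed delta-ppm.
# Haliclamine A does not follow the THP-THP rule (its printed fragments
# are pyridinium-type) and is encoded from its printed formula directly.
# ---------------------------------------------------------------------------

_CURATED_RULE_ROWS = [
    # (name, class, chains, printed formula, mh, m2h, fragments, dppm)
    ("Cyclostellettamine P", "cyclostellettamine", (9, 11), "C30H49N2", 437.3896,
     218.1909, [("C14H22N", 204.1752, 1), ("C16H26N", 232.2065, 1)], 1),
    ("Cyclostellettamine Q", "cyclostellettamine", (10, 11), "C31H51N2", 451.4052,
     225.1909, [("C15H24N", 218.1909, 1), ("C16H26N", 232.2065, 1)], 3),
    ("Cyclostellettamine N", "cyclostellettamine", (9, 10), "C29H47N2", 423.3779,
     211.1803, [("C14H22N", 204.1752, 1), ("C15H24N", 218.1909, 1)], 9),
    ("Cyclostellettamine G", "cyclostellettamine", (11, 12), "C33H55N2", 479.4365,
     239.2110, [("C16H26N", 232.2065, 1), ("C17H28N", 246.1752, 1)], 10),
    ("Cyclostellettamine A", "cyclostellettamine", (12, 12), "C34H57N2", 493.4522,
     246.2150, [("C17H29N", 261.2331, 1), ("C17H29N", 261.2331, 1)], 3),
    ("Haliclamine C", "haliclamine", (9, 11), "C30H55N2", 443.4365,
     222.2222, [("C14H26N", 208.2065, 1), ("C16H30N", 236.2378, 1)], 8),
    ("Haliclamine D", "haliclamine", (10, 11), "C31H57N2", 457.4522,
     229.2259, [("C15H28N", 222.2222, 1), ("C16H30N", 236.2378, 1)], 6),
    ("Haliclamine E", "haliclamine", (9, 10), "C29H53N2", 429.4209,
     215.2089, [("C14H26N", 208.2065, 1), ("C15H28N", 222.2222, 1)], 1),
    ("Haliclamine H", "haliclamine", (10, 12), "C32H59N2", 471.4678,
     236.2378, [("C15H28N", 222.2222, 1), ("C17H32N", 250.2535, 1)], 4),
]


def _curated_from_rule(row) -> ApaCompound:
    name, cls, chains, formula, mh, m2h, frags, dppm = row
    compound = _MAKERS[cls](*chains)
    compound.name = name
    compound.curated = True
    label_2 = "[M]2+" if cls == "cyclostellettamine" else "[M+2H]2+"
    compound.printed = {
        "formula": formula,
        "[M+H]+": mh,
        label_2: m2h,
        "fragments": frags,
        "delta_ppm": dppm,
    }
    # attach printed fragment m/z where the printed formula matches the rule
    attached: list[FragmentIon] = []
    printed_left = list(frags)
    for frag in compound.predicted_fragments:
        mz_printed = None
        for i, (pf, pmz, pz) in enumerate(printed_left):
            if frag.role != "diagnostic" and parse_formula(pf) == frag.formula and pz == frag.charge:
                mz_printed = pmz
                del printed_left[i]
                break
        attached.append(
            FragmentIon(frag.role, frag.formula, frag.charge, frag.parent_moiety, mz_printed)
        )
    compound.predicted_fragments = attached
    return compound


def _curated_haliclamine_a() -> ApaCompound:
    # Printed [M+H]+ form C31H53N2 -> neutral C31H52N2; printed fragments
    # are pyridinium-type with 9- and 12-carbon chains, so both diagnostics
    # are carried.  Stored as a curated-only entry, not rule-generated.
    neutral = parse_formula("C31H52N2")
    ions = [
        IonSpecies(add_protons(neutral, 1), 1, "[M+H]+"),
        IonSpecies(add_protons(neutral, 2), 2, "[M+2H]2+"),
    ]
    frags = _order_f1_f2(
        [_pyr_fragment(9, 204.1752), _pyr_fragment(12, 246.2222)]
    )
    compound = ApaCompound(
        name="Haliclamine A",
        apa_class="haliclamine",
        moieties={"Pyr": 1, "THP": 1},
        topology="cyclic-dimer",
        chain_lengths=(9, 12),
        base_formula=neutral,
        ion_species=ions,
        predicted_fragments=[THP_DIAGNOSTIC, PYR_DIAGNOSTIC] + frags,
        curated=True,
        rule_generated=False,
        printed={
            "formula": "C31H53N2",
            "[M+H]+": 453.4209,
            "[M+2H]2+": 227.2113,
            "fragments": [("C14H22N", 204.1752, 1), ("C17H28N", 246.2222, 1)],
            "delta_ppm": 8,
        },
    )
    return compound


def _curated_viscosamine_c() -> ApaCompound:
    compound = make_viscosamine(13, 13, 13)
    compound.name = "Viscosamine C"
    compound.curated = True
    compound.printed = {
        "formula": "C54H90N3",
        "[M]3+": 260.2382,
        "fragments": [("C54H91N3", 390.8637, 2), ("C54H89N3", 389.8637, 2)],
    }
    compound.predicted_fragments = compound.predicted_fragments + _order_f1_f2([
        FragmentIon("F1", parse_formula("C54H91N3"), 2, "Pyr", 390.8637),
        FragmentIon("F1", parse_formula("C54H89N3"), 2, "Pyr", 389.8637),
    ])
    return compound


def _curated_viscosaline(name, chains, printed_formula, mh, d1, d2, frags, dppm) -> ApaCompound:
    compound = make_viscosaline(*chains)
    compound.name = name
    compound.curated = True
    compound.printed = {
        "formula": printed_formula,
        "[M]+": mh,
        "[M+H]2+": d2,
        "fragments": frags,
        "delta_ppm": dppm,
    }
    # first printed doubly charged species: composition not derivable
    compound.printed_only_ions = [("[M']2+", d1)]
    compound.predicted_fragments = compound.predicted_fragments + _order_f1_f2([
        FragmentIon("F1", parse_formula(f), z, "Pyr", mz) for f, mz, z in frags
    ])
    return compound


def curated_library() -> "MassLibrary":
    """The thirteen curated reference 3-APA compounds."""
    entries = [_curated_from_rule(row) for row in _CURATED_RULE_ROWS[:5]]
    entries.append(_curated_haliclamine_a())
    entries.extend(_curated_from_rule(row) for row in _CURATED_RULE_ROWS[5:])
    entries.append(_curated_viscosamine_c())
    entries.append(
        _curated_viscosaline(
            "Viscosaline B2", (12, 13), "C38H64N3O2", 594.4999, 246.2191, 297.7537,
            [("C35H58N2", 253.2321, 2), ("C36H61N3", 267.7429, 2)], 4,
        )
    )
    entries.append(
        # printed formula C39H67N3O2 is one H heavier than the printed
        # mass 608.5155 supports; the modeled entry uses C39H66N3O2
        _curated_viscosaline(
            "Viscosaline C", (13, 13), "C39H67N3O2", 608.5155, 253.2264, 304.7621,
            [("C36H60N2", 260.2376, 2), ("C37H63N3", 274.7509, 2)], 5,
        )
    )
    return MassLibrary(entries)


def expand_homologs(
    chain_range: tuple[int, int] = DEFAULT_CHAIN_RANGE,
    classes: Iterable[ApaClass] = ("cyclostellettamine", "haliclamine", "viscosamine", "viscosaline"),
    merge_curated: bool = True,
) -> "MassLibrary":
    """All unordered chain-length combinations per class in the range.

    Entries are deduplicated by (class, sorted chains).  When
    ``merge_curated`` is set, generated entries matching a curated
    (class, chains) pair are replaced by the curated entry, keeping the
    curated name and printed reference values.
    """
    lo, hi = chain_range
    if lo > hi or lo < 1 or hi > 30:
        raise ValueError(f"invalid chain range {chain_range}")
    curated = {(c.apa_class, c.chain_lengths): c for c in curated_library().entries
               if c.rule_generated} if merge_curated else {}
    entries: list[ApaCompound] = []
    lengths = range(lo, hi + 1)
    for cls in classes:
        arity = 3 if cls == "viscosamine" else 2
        for chains in combinations_with_replacement(lengths, arity):
            key = (cls, tuple(sorted(chains)))
            entries.append(curated.get(key) or _MAKERS[cls](*chains))
    return MassLibrary(entries)


@dataclass(frozen=True)
class LibraryHit:
    compound: ApaCompound
    ion_label: str
    charge: int
    library_mz: float
    ppm_error: float


class MassLibrary:
    """Indexed collection of compounds for m/z lookup.

    The index maps every ion of every entry to (compound, ion label).
    ``use_printed`` switches matching from recomputed, self-consistent
    m/z values to the printed reference values where those exist.
    """

    def __init__(self, entries: Sequence[ApaCompound], use_printed: bool = False):
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate compound names: {dupes}")
        self.entries = list(entries)
        self.use_printed = use_printed
        self._index: list[tuple[float, ApaCompound, str, int]] = []
        for comp in self.entries:
            for ion in comp.ion_species:
                mz = comp.printed.get(ion.label, ion.mz) if use_printed else ion.mz
                self._index.append((mz, comp, ion.label, ion.charge))
            if use_printed:
                for label, mz in comp.printed_only_ions:
                    self._index.append((mz, comp, label, 2))
        self._index.sort(key=lambda t: t[0])
        self._mzs = [t[0] for t in self._index]

    @property
    def size(self) -> int:
        return len(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str) -> ApaCompound:
        for comp in self.entries:
            if comp.name == name:
                return comp
        raise KeyError(name)

    def lookup(self, mz: float, ppm_tol: float) -> list[LibraryHit]:
        """All library ions within ``ppm_tol`` of ``mz``, by |ppm error|."""
        if ppm_tol < 0:
            raise ValueError("ppm_tol must be >= 0")
        half = mz * ppm_tol * 1e-6
        lo = bisect.bisect_left(self._mzs, mz - half)
        hi = bisect.bisect_right(self._mzs, mz + half)
        hits = []
        for lib_mz, comp, label, charge in self._index[lo:hi]:
            ppm = (mz - lib_mz) / lib_mz * 1e6
            if abs(ppm) <= ppm_tol:
                hits.append(LibraryHit(comp, label, charge, lib_mz, ppm))
        hits.sort(key=lambda h: abs(h.ppm_error))
        return hits

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = []
        for c in self.entries:
            payload.append({
                "name": c.name,
                "apa_class": c.apa_class,
                "moieties": c.moieties,
                "topology": c.topology,
                "chain_lengths": list(c.chain_lengths),
                "beta_alanine_units": c.beta_alanine_units,
                "base_formula": c.base_formula.serialize(),
                "ions": [
                    {"label": i.label, "charge": i.charge,
                     "formula": i.ion_formula.serialize()}
                    for i in c.ion_species
                ],
                "fragments": [
                    {"role": f.role, "formula": f.formula.serialize(),
                     "charge": f.charge, "parent_moiety": f.parent_moiety,
                     "mz_printed": f.mz_printed}
                    for f in c.predicted_fragments
                ],
                "curated": c.curated,
                "rule_generated": c.rule_generated,
                "printed": c.printed,
                "printed_only_ions": c.printed_only_ions,
            })
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path, use_printed: bool = False) -> "MassLibrary":
        payload = json.loads(Path(path).read_text())
        entries = []
        for rec in payload:
            printed = dict(rec["printed"])
            if "fragments" in printed:
                printed["fragments"] = [tuple(f) for f in printed["fragments"]]
            comp = ApaCompound(
                name=rec["name"],
                apa_class=rec["apa_class"],
                moieties=dict(rec["moieties"]),
                topology=rec["topology"],
                chain_lengths=tuple(rec["chain_lengths"]),
                base_formula=parse_formula(rec["base_formula"]),
                ion_species=[
                    IonSpecies(parse_formula(i["formula"]), i["charge"], i["label"])
                    for i in rec["ions"]
                ],
                predicted_fragments=[
                    FragmentIon(f["role"], parse_formula(f["formula"]), f["charge"],
                                f["parent_moiety"], f["mz_printed"])
                    for f in rec["fragments"]
                ],
                beta_alanine_units=rec["beta_alanine_units"],
                curated=rec["curated"],
                rule_generated=rec["rule_generated"],
                printed=printed,
                printed_only_ions=[tuple(t) for t in rec["printed_only_ions"]],
            )
            entries.append(comp)
        return cls(entries, use_printed=use_printed)

    def to_tsv(self, path: str | Path) -> None:
        """Flat export: one row per ion and one row per fragment."""
        cols = ("name\tclass\ttopology\tchains\tformula\tion_label\tcharge\t"
                "mz_recomputed\tmz_printed\tfragment_role\tfragment_formula\tfragment_mz")
        lines = [cols]
        for c in self.entries:
            chains = ",".join(map(str, c.chain_lengths))
            for ion in c.ion_species:
                printed = c.printed.get(ion.label, "")
                lines.append(
                    f"{c.name}\t{c.apa_class}\t{c.topology}\t{chains}\t"
                    f"{c.base_formula.serialize()}\t{ion.label}\t{ion.charge}\t"
                    f"{ion.mz:.6f}\t{printed}\t\t\t"
                )
            for frag in c.predicted_fragments:
                lines.append(
                    f"{c.name}\t{c.apa_class}\t{c.topology}\t{chains}\t"
                    f"{c.base_formula.serialize()}\t\t{frag.charge}\t"
                    f"\t{frag.mz_printed if frag.mz_printed is not None else ''}\t"
                    f"{frag.role}\t{frag.formula.serialize()}\t{frag.mz:.6f}"
                )
        Path(path).write_text("\n".join(lines) + "\n")
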