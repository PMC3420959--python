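"""Two-round Golden Gate assembly planning for RVD repeat arrays.

Round 1 builds two intermediate arrays — repeats 1-10 and repeats
11..(n-1). Round 2 joins the two arrays, the n-th (last) repeat module and
the destination expression backbone: Left monomers go into pCS2TAL3DD
(Flag-tagged, FokI DD) and Right monomers into pCS2TAL3RR (HA-tagged,
FokI RR), so the assembled pair can only cut as a DD+RR heterodimer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .design import RvdArray, RvdModule

BACKBONES = {"Left": "pCS2TAL3DD", "Right": "pCS2TAL3RR"}
#: epitope tag and FokI variant carried by each destination backbone
BACKBONE_FEATURES = {
    "pCS2TAL3DD": {"tag": "Flag", "fokI": "DD"},
    "pCS2TAL3RR": {"tag": "HA", "fokI": "RR"},
}

#: length of one 34-aa repeat in nucleotides (annotation only)
DEFAULT_BP_PER_REPEAT = 102

ROUTINE_RANGE = (16, 21)
SUPPORTED_RANGE = (12, 31)


@dataclass(frozen=True)
class ModuleSelection:
    position: int  # 1-based index within the full array
    rvd: RvdModule
    round1_slot: str  # "arrayA" | "arrayB" | "last_repeat"


@dataclass(frozen=True)
class AssemblyPlan:
    n: int
    side: str
    array_a: tuple[ModuleSelection, ...]  # repeats 1-10
    array_b: tuple[ModuleSelection, ...]  # repeats 11..n-1
    last_repeat: ModuleSelection  # repeat n
    destination: str

    @property
    def round1(self) -> tuple[tuple[ModuleSelection, ...], tuple[ModuleSelection, ...]]:
        return (self.array_a, self.array_b)

    def recomposed_codes(self) -> tuple[str, ...]:
        sels = list(self.array_a) + list(self.array_b) + [self.last_repeat]
        return tuple(s.rvd.code for s in sels)


@dataclass(frozen=True)
class ConstructFeature:
    name: str
    kind: str
    length_bp: int | None = None  # None = symbolic (sequence not modelled)
    note: str = ""


@dataclass(frozen=True)
class ConstructMap:
    """Schematic feature map of an assembled TALEN expression construct."""

    construct_id: str
    destination: str
    n_repeats: int
    features: tuple[ConstructFeature, ...]


@dataclass(frozen=True)
class ValidationReport:
    passed: bool
    issues: tuple[str, ...] = field(default_factory=tuple)


def assign_backbone(side: str) -> str:
    """Destination backbone for a monomer: Left -> DD, Right -> RR."""
    if side not in BACKBONES:
        raise ValueError(f"side must be 'Left' or 'Right', got {side!r}")
    return BACKBONES[side]


def plan_golden_gate(arr: RvdArray) -> AssemblyPlan:
    """Partition an RVD array into the two-round cloning recipe.

    Requires 12 <= n <= 31: array A holds repeats 1-10, array B holds
    repeats 11..n-1 (non-empty only if n >= 12), and repeat n enters at
    the second round. Arrays outside the routine 16-21 range trigger a
    warning but are planned.
    """
    n = arr.n
    lo, hi = SUPPORTED_RANGE
    if not (lo <= n <= hi):
        raise ValueError(
            f"two-round assembly supports {lo} <= n <= {hi} repeats "
            f"(array B must hold repeats 11..n-1); got n={n}"
        )
    if not (ROUTINE_RANGE[0] <= n <= ROUTINE_RANGE[1]):
        warnings.warn(
            f"n={n} repeats is outside the routine {ROUTINE_RANGE[0]}-"
            f"{ROUTINE_RANGE[1]} design range",
            stacklevel=2,
        )
    sels = [
        ModuleSelection(
            position=i + 1,
            rvd=m,
            round1_slot=(
                "arrayA" if i < 10 else "arrayB" if i < n - 1 else "last_repeat"
            ),
        )
        for i, m in enumerate(arr.modules)
    ]
    return AssemblyPlan(
        n=n,
        side=arr.side,
        array_a=tuple(sels[:10]),
        array_b=tuple(sels[10 : n - 1]),
        last_repeat=sels[n - 1],
        destination=assign_backbone(arr.side),
    )


def validate_plan(plan: AssemblyPlan, arr: RvdArray) -> ValidationReport:
    """In-silico stand-in for sequencing verification of an assembly."""
    issues: list[str] = []
    if plan.n != arr.n:
        issues.append(f"plan n={plan.n} but array has {arr.n} modules")
    expected = arr.codes
    got = plan.recomposed_codes()
    for pos, (e, g) in enumerate(zip(expected, got), start=1):
        if e != g:
            issues.append(f"position {pos}: expected {e}, plan yields {g}")
    if len(got) != len(expected):
        issues.append(f"recomposition has {len(got)} modules, expected {len(expected)}")
    if len(plan.array_a) != min(10, plan.n):
        issues.append(f"array A holds {len(plan.array_a)} modules, expected 10")
    for sel in plan.array_a:
        if not (1 <= sel.position <= 10):
            issues.append(f"array A contains out-of-slot position {sel.position}")
    for sel in plan.array_b:
        if not (11 <= sel.position <= plan.n - 1):
            issues.append(f"array B contains out-of-slot position {sel.position}")
    if plan.last_repeat.position != plan.n:
        issues.append(
            f"last repeat is position {plan.last_repeat.position}, expected {plan.n}"
        )
    if BACKBONES.get(plan.side) != plan.destination:
        issues.append(
            f"{plan.side} monomer routed to {plan.destination}; "
            f"expected {BACKBONES.get(plan.side)}"
        )
    return ValidationReport(passed=not issues, issues=tuple(issues))


def build_construct_map(
    plan: AssemblyPlan, bp_per_repeat: int = DEFAULT_BP_PER_REPEAT
) -> ConstructMap:
    """Schematic map of the expression construct an assembly produces.

    Feature order is fixed: promoter (CMV/SP6), NLS, epitope tag, TAL
    N-terminal domain (136 aa), RVD repeat block (n x ~102 bp), TAL
    C-terminal domain (63 aa), FokI variant, SV40 polyA, then the NotI
    linearization site used for run-off in vitro transcription. Extents
    are approximate; the vector sequence itself is not modelled.
    """
    bb = BACKBONE_FEATURES[plan.destination]
    features = (
        ConstructFeature("CMV/SP6", "promoter", None, "vector-provided"),
        ConstructFeature("NLS", "localization_signal", None),
        ConstructFeature(bb["tag"], "epitope_tag", None),
        ConstructFeature("TAL-N'", "tale_domain", 136 * 3, "136 aa"),
        ConstructFeature(
            "RVD_repeats",
            "repeat_block",
            plan.n * bp_per_repeat,
            f"{plan.n} repeats x {bp_per_repeat} bp",
        ),
        ConstructFeature("TAL-C'", "tale_domain", 63 * 3, "63 aa"),
        ConstructFeature(f"FokI({bb['fokI']})", "nuclease_domain", None),
        ConstructFeature("SV40pA", "polyA_signal", None),
        ConstructFeature("NotI", "linearization_site", None, "downstream of unit"),
    )
    return ConstructMap(
        construct_id=f"{plan.side}_TALEN_{plan.destination}",
        destination=plan.destination,
        n_repeats=plan.n,
        features=features,
    )


def construct_map_to_gff3(cmap: ConstructMap) -> str:
    """Render a construct map as GFF3 with symbolic coordinates.

    Features without a modelled length get a nominal 1-bp extent so the
    record stays valid GFF3; real extents appear where derivable.
    """
    lines = ["##gff-version 3"]
    pos = 1
    for f in cmap.features:
        length = f.length_bp if f.length_bp else 1
        attrs = f"ID={f.name};kind={f.kind}"
        if f.note:
            attrs += f";Note={f.note}"
        if f.length_bp is None:
            attrs += ";symbolic=true"
        lines.append(
            "\t".join(
                [
                    cmap.construct_id,
                    "talenkit",
                    f.kind,
                    str(pos),
                    str(pos + length - 1),
                    ".",
                    "+",
                    ".",
                    attrs,
                ]
            )
        )
        pos += length
    return "\n".join(lines) + "\n"


def plan_summary(plan: AssemblyPlan) -> str:
    """Human-readable two-round recipe."""

    def fmt(sels: Sequence[ModuleSelection]) -> str:
        return ",".join(s.rvd.code for s in sels)

    return (
        f"{plan.side} TALEN, n={plan.n} repeats -> {plan.destination}\n"
        f"  round 1: array A (repeats 1-10):   {fmt(plan.array_a)}\n"
        f"           array B (repeats 11-{plan.n - 1}): {fmt(plan.array_b)}\n"
        f"  round 2: array A + array B + last repeat "
        f"({plan.last_repeat.rvd.code}) -> {plan.destination}\n"
    )
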