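"""Base-pair-resolution descriptions of DNA origami nanobeams.

A nanobeam is a set of parallel double helices joined by Holliday-junction
(HJ) crossovers, with optional backbone nicks between consecutive staple
strands.  This module builds :class:`NanobeamDesign` objects for

* the two-helix DX-tile constructs (C85/C170, ligated or nicked) whose axial
  stiffness was measured by flow stretching, and
* idealized multi-helix bundles (honeycomb or square packing) with prescribed
  per-helix junction and nick densities.

Only topology matters here: helix count, bp count, and the axial positions of
junctions and nicks.  Sequence content is never modelled.

Positions are 0-based bp indices along the helix axis.  A position ``p``
refers to the boundary between bp ``p-1`` and bp ``p``; the elastic element
"centered" on it is bp element ``p`` (see :mod:`nanobeam.mechanics`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ValidationError

#: Default axial rise of B-form DNA, nm per bp.
DEFAULT_RISE_NM = 0.34

#: bp of one helical double-crossover repeat used to express densities
#: ("per 21 bp" in design tables; two turns of B-DNA).
REPEAT_BP = 21

#: Minimum per-helix gap (bp) between junction participations enforced by the
#: bundle builder, equal to the default HJ element span so degraded blocks
#: never overlap.
MIN_JUNCTION_GAP_BP = 5

#: Minimum |nick - junction| distance (bp) so a 1 bp nick element clears a
#: 5 bp HJ block.
MIN_NICK_GAP_BP = 3

PACKINGS = ("pair", "honeycomb", "square")


@dataclass(frozen=True)
class NanobeamDesign:
    """Topological description of a multi-helix DNA nanobeam.

    Attributes
    ----------
    n_helices:
        Number of parallel double helices.
    bp_per_helix:
        Base pairs per helix (all helices equal length).
    rise_per_bp:
        Axial rise per bp in nm (0.34 for B-form DNA).
    junction_sites:
        Sorted tuples ``((helix_a, helix_b), bp_position)`` — each entry is
        one Holliday-junction crossover rigidly coupling the two helices at
        that axial position.
    nick_sites:
        Tuples ``(helix, bp_position)`` — backbone discontinuities.
    packing:
        Cross-section lattice: ``pair`` (two helices), ``honeycomb`` or
        ``square``.
    name:
        Optional preset label (e.g. ``"C170L"``).
    """

    n_helices: int
    bp_per_helix: int
    junction_sites: tuple[tuple[tuple[int, int], int], ...] = ()
    nick_sites: tuple[tuple[int, int], ...] = ()
    rise_per_bp: float = DEFAULT_RISE_NM
    packing: str = "pair"
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_helices < 1:
            raise ValidationError("n_helices must be >= 1")
        if self.bp_per_helix < 1:
            raise ValidationError("bp_per_helix must be >= 1")
        if self.rise_per_bp <= 0:
            raise ValidationError("rise_per_bp must be > 0")
        if self.packing not in PACKINGS:
            raise ValidationError(f"unknown packing {self.packing!r}")
        object.__setattr__(
            self,
            "junction_sites",
            tuple(sorted(((tuple(sorted(pair)), int(pos))
                          for pair, pos in self.junction_sites),
                         key=lambda s: (s[1], s[0]))),
        )
        object.__setattr__(
            self, "nick_sites",
            tuple(sorted((int(h), int(p)) for h, p in self.nick_sites)))
        seen: dict[tuple[int, int], int] = {}
        for (a, b), pos in self.junction_sites:
            if not (0 <= a < self.n_helices and 0 <= b < self.n_helices) or a == b:
                raise ValidationError(f"junction pair ({a},{b}) invalid")
            if not 0 < pos < self.bp_per_helix:
                raise ValidationError(
                    f"junction position {pos} not strictly interior")
            if seen.get((a, b)) == pos:
                raise ValidationError(
                    f"duplicate junction at {pos} for pair ({a},{b})")
            seen[(a, b)] = pos
        nick_set = set()
        for h, pos in self.nick_sites:
            if not 0 <= h < self.n_helices:
                raise ValidationError(f"nick helix {h} out of range")
            if not 0 < pos < self.bp_per_helix:
                raise ValidationError(
                    f"nick position {pos} not strictly interior")
            if (h, pos) in nick_set:
                raise ValidationError(f"duplicate nick at ({h},{pos})")
            nick_set.add((h, pos))

    @property
    def length_nm(self) -> float:
        """Contour length in nm (bp count times rise)."""
        return self.bp_per_helix * self.rise_per_bp

    @property
    def n_junctions(self) -> int:
        return len(self.junction_sites)

    @property
    def n_nicks(self) -> int:
        return len(self.nick_sites)

    def helix_junction_positions(self, helix: int) -> list[int]:
        """Sorted junction positions in which ``helix`` participates."""
        return sorted(pos for pair, pos in self.junction_sites if helix in pair)

    def helix_nick_positions(self, helix: int) -> list[int]:
        return sorted(pos for h, pos in self.nick_sites if h == helix)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_helices": self.n_helices,
            "packing": self.packing,
            "bp_per_helix": self.bp_per_helix,
            "rise_per_bp": self.rise_per_bp,
            "junctions": [[a, b, pos] for (a, b), pos in self.junction_sites],
            "nicks": [[h, pos] for h, pos in self.nick_sites],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NanobeamDesign":
        return cls(
            n_helices=d["n_helices"],
            bp_per_helix=d["bp_per_helix"],
            junction_sites=tuple(((a, b), p) for a, b, p in d.get("junctions", [])),
            nick_sites=tuple((h, p) for h, p in d.get("nicks", [])),
            rise_per_bp=d.get("rise_per_bp", DEFAULT_RISE_NM),
            packing=d.get("packing", "pair"),
            name=d.get("name", ""),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "NanobeamDesign":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Two-helix DX-tile builder
# ---------------------------------------------------------------------------

def two_helix_junction_positions(bp_per_helix: int,
                                 junction_spacing_bp: int) -> list[int]:
    """Axial junction positions for a periodic two-helix DX design.

    Crossovers sit at multiples of the spacing, ``spacing * i`` for
    ``i = 1..n_j``, keeping only sites whose trailing segment is at least half
    a spacing (so the design ends on a representative partial repeat).  This
    convention reproduces the printed counts for the measured constructs:
    3600 bp with 21 bp spacing gives 170 crossovers, 42 bp spacing gives 85.
    """
    return [junction_spacing_bp * i
            for i in range(1, bp_per_helix // junction_spacing_bp + 1)
            if 2 * (bp_per_helix - junction_spacing_bp * i) >= junction_spacing_bp]


def build_two_helix(bp_per_helix: int, junction_spacing_bp: int,
                    ligated: bool = False, rise_per_bp: float = DEFAULT_RISE_NM,
                    name: str = "") -> NanobeamDesign:
    """Build a two-helix DX-tile nanobeam with periodic crossovers.

    Parameters
    ----------
    bp_per_helix:
        Base pairs per helix (3600 for the measured 1224 nm constructs).
    junction_spacing_bp:
        Crossover period in bp (21 for C170, 42 for C85).
    ligated:
        If True all staple nicks are sealed (no nick sites); otherwise each
        helix is nicked at the midpoint of the interval following every
        crossover, in both helices at the same axial position, giving exactly
        ``2 * n_junctions`` nicks.

    A spacing not smaller than the helix length yields a valid design with
    zero junctions.
    """
    if bp_per_helix < 1:
        raise ValidationError("bp_per_helix must be >= 1")
    if junction_spacing_bp < 2:
        raise ValidationError("junction_spacing_bp must be >= 2")
    positions = two_helix_junction_positions(bp_per_helix, junction_spacing_bp)
    junctions = tuple(((0, 1), p) for p in positions)
    nicks: tuple[tuple[int, int], ...] = ()
    if not ligated:
        nick_pos = []
        for i, p in enumerate(positions):
            nxt = positions[i + 1] if i + 1 < len(positions) else bp_per_helix
            nick_pos.append((p + nxt) // 2)
        nicks = tuple((h, p) for p in nick_pos for h in (0, 1))
    return NanobeamDesign(
        n_helices=2, bp_per_helix=bp_per_helix, junction_sites=junctions,
        nick_sites=nicks, rise_per_bp=rise_per_bp, packing="pair", name=name)


# ---------------------------------------------------------------------------
# Multi-helix bundle builder
# ---------------------------------------------------------------------------

def packing_interfaces(n_helices: int, packing: str) -> list[tuple[int, int]]:
    """Adjacency (interface) edges of the bundle cross-section.

    ``pair`` is only valid for 1 or 2 helices.  ``honeycomb`` with n >= 3 is
    idealized as a closed ring of n interfaces (each helix touches two
    neighbours), matching the 6-helix bundle's ring of 6 interfaces.
    ``square`` arranges helices on the most square rows x cols grid with
    nearest-neighbour interfaces.
    """
    if n_helices == 1:
        return []
    if n_helices == 2:
        return [(0, 1)]
    if packing == "pair":
        raise ValidationError("pair packing requires n_helices <= 2")
    if packing == "honeycomb":
        return [(i, (i + 1) % n_helices) for i in range(n_helices)]
    if packing == "square":
        rows = max(d for d in range(1, int(n_helices ** 0.5) + 1)
                   if n_helices % d == 0)
        cols = n_helices // rows
        edges = []
        for r in range(rows):
            for c in range(cols):
                i = r * cols + c
                if c + 1 < cols:
                    edges.append((i, i + 1))
                if r + 1 < rows:
                    edges.append((i, i + cols))
        return edges
    raise ValidationError(f"unknown packing {packing!r}")


def _edge_quotas(edges: Sequence[tuple[int, int]], n_helices: int,
                 per_helix_target: int) -> list[int]:
    """Per-interface junction counts approximating a uniform per-helix
    participation target.

    Greedy b-matching first places junctions where both helices are below
    target; a second pass tops up the least-loaded interfaces until the
    total participation budget ``n_helices * target`` is spent.  On
    interface graphs where uniformity is infeasible (bipartite with unequal
    parts, e.g. a 3x3 square grid) the smaller part carries the excess, so
    the bundle-average density is preserved.
    """
    quota = [0] * len(edges)
    count = [0] * n_helices
    while True:
        best, best_score = None, 0
        for k, (a, b) in enumerate(edges):
            da = per_helix_target - count[a]
            db = per_helix_target - count[b]
            if da >= 1 and db >= 1:
                score = min(da, db) * 1000 + da + db - quota[k]
                if score > best_score:
                    best, best_score = k, score
        if best is None:
            break
        quota[best] += 1
        a, b = edges[best]
        count[a] += 1
        count[b] += 1
    target_junctions = round(n_helices * per_helix_target / 2)
    while sum(quota) < target_junctions:
        k = min(range(len(edges)),
                key=lambda k: (count[edges[k][0]] + count[edges[k][1]],
                               max(count[edges[k][0]], count[edges[k][1]]),
                               k))
        quota[k] += 1
        a, b = edges[k]
        count[a] += 1
        count[b] += 1
    return quota


def _edge_colors(edges: Sequence[tuple[int, int]]) -> tuple[list[int], int]:
    """Greedy proper edge coloring (incident edges get distinct colors)."""
    colors: list[int] = []
    for k, (a, b) in enumerate(edges):
        used = {colors[j] for j, (x, y) in enumerate(edges[:k])
                if {x, y} & {a, b}}
        c = 0
        while c in used:
            c += 1
        colors.append(c)
    return colors, (max(colors) + 1 if colors else 1)


def _repair_min_gaps(positions: dict[int, list[int]],
                     helix_of: dict[int, tuple[int, int]],
                     bp: int, min_gap: int) -> dict[int, int]:
    """Nudge junctions forward so every helix's participations are >= min_gap
    apart.  ``positions`` maps junction id -> [pos]; ``helix_of`` maps
    junction id -> (helix_a, helix_b).  Returns junction id -> position."""
    pos = {jid: p[0] for jid, p in positions.items()}
    for _ in range(10 * max(1, len(pos))):
        moved = False
        by_helix: dict[int, list[int]] = {}
        for jid, (a, b) in helix_of.items():
            by_helix.setdefault(a, []).append(jid)
            by_helix.setdefault(b, []).append(jid)
        for h, jids in by_helix.items():
            jids.sort(key=lambda j: pos[j])
            for j1, j2 in zip(jids, jids[1:]):
                gap = pos[j2] - pos[j1]
                if gap < min_gap:
                    shift = min_gap - gap
                    if pos[j2] + shift >= bp - min_gap:
                        raise ValidationError(
                            "cannot schedule junctions: density too high for "
                            f"min gap {min_gap} bp on helix {h}")
                    pos[j2] += shift
                    moved = True
        if not moved:
            return pos
    raise ValidationError("junction schedule repair did not converge")


def build_bundle(n_helices: int, packing: str, length_nm: float,
                 junctions_per_helix_per_21bp: float,
                 nicks_per_helix_per_21bp: float,
                 rise_per_bp: float = DEFAULT_RISE_NM,
                 name: str = "") -> NanobeamDesign:
    """Build an idealized multi-helix bundle with prescribed densities.

    Junction participations are distributed uniformly over the interfaces of
    the packing's adjacency graph, phase-staggered between interfaces, so
    each helix participates in ``junctions_per_helix_per_21bp`` crossovers
    per 21 bp (within rounding).  Nicks are placed per helix at the stated
    density, at midpoints between that helix's junction participations.

    The axial response depends only on the per-helix counts, not on the exact
    phases (see the homogenized oracle in :mod:`nanobeam.mechanics`).
    """
    if n_helices < 1:
        raise ValidationError("n_helices must be >= 1")
    if junctions_per_helix_per_21bp < 0 or nicks_per_helix_per_21bp < 0:
        raise ValidationError("densities must be >= 0")
    if length_nm <= 0:
        raise ValidationError("length_nm must be > 0")
    bp = int(round(length_nm / rise_per_bp))
    edges = packing_interfaces(n_helices, packing)
    per_helix = int(round(junctions_per_helix_per_21bp * bp / REPEAT_BP))

    junctions: tuple[tuple[tuple[int, int], int], ...] = ()
    if edges and per_helix > 0:
        quotas = _edge_quotas(edges, n_helices, per_helix)
        colors, n_colors = _edge_colors(edges)
        cand: dict[int, list[int]] = {}
        helix_of: dict[int, tuple[int, int]] = {}
        jid = 0
        for k, (a, b) in enumerate(edges):
            q = quotas[k]
            if q == 0:
                continue
            phase = (colors[k] + 0.5) / n_colors
            period = bp / q
            for i in range(q):
                p = int(round((i + phase) * period))
                p = min(max(p, MIN_JUNCTION_GAP_BP), bp - MIN_JUNCTION_GAP_BP)
                cand[jid] = [p]
                helix_of[jid] = (a, b)
                jid += 1
        final = _repair_min_gaps(cand, helix_of, bp, MIN_JUNCTION_GAP_BP)
        junctions = tuple((helix_of[j], p) for j, p in final.items())

    nicks: list[tuple[int, int]] = []
    n_nicks_per_helix = int(round(nicks_per_helix_per_21bp * bp / REPEAT_BP))
    if n_nicks_per_helix > 0:
        per_helix_pos = {h: [] for h in range(n_helices)}
        for (a, b), p in junctions:
            per_helix_pos[a].append(p)
            per_helix_pos[b].append(p)
        for h in range(n_helices):
            jpos = sorted(per_helix_pos[h])
            if len(jpos) >= 2:
                mids = [(p1 + p2) // 2 for p1, p2 in zip(jpos, jpos[1:])
                        if min((p1 + p2) // 2 - p1, p2 - (p1 + p2) // 2)
                        >= MIN_NICK_GAP_BP]
            else:
                mids = []
            if len(mids) >= n_nicks_per_helix:
                idx = [round(i * (len(mids) - 1) / max(1, n_nicks_per_helix - 1))
                       for i in range(n_nicks_per_helix)] \
                    if n_nicks_per_helix > 1 else [len(mids) // 2]
                chosen = sorted({mids[i] for i in idx})
            else:
                # Sparse-junction helix: fall back to uniform placement away
                # from junction blocks.
                chosen = []
                step = bp / (n_nicks_per_helix + 1)
                for i in range(1, n_nicks_per_helix + 1):
                    p = int(round(i * step))
                    while any(abs(p - q) < MIN_NICK_GAP_BP for q in jpos):
                        p += 1
                    if 0 < p < bp:
                        chosen.append(p)
            nicks.extend((h, p) for p in chosen)

    return NanobeamDesign(
        n_helices=n_helices, bp_per_helix=bp, junction_sites=junctions,
        nick_sites=tuple(nicks), rise_per_bp=rise_per_bp, packing=packing,
        name=name)


# ---------------------------------------------------------------------------
# Named presets
# ---------------------------------------------------------------------------

#: bp per helix of the measured two-helix constructs: 1224 nm / 0.34 nm per
#: bp, i.e. half the M13mp18 scaffold folded back on itself.
CONSTRUCT_BP = 3600

_PRESET_BUILDERS = {
    "C85L": lambda: build_two_helix(CONSTRUCT_BP, 42, ligated=True, name="C85L"),
    "C85N": lambda: build_two_helix(CONSTRUCT_BP, 42, ligated=False, name="C85N"),
    "C170L": lambda: build_two_helix(CONSTRUCT_BP, 21, ligated=True, name="C170L"),
    "C170N": lambda: build_two_helix(CONSTRUCT_BP, 21, ligated=False, name="C170N"),
    # Literature 6- and 10-helix bundles: lengths and per-helix densities
    # (2 junction participations and 0.5 nicks per helix per 21 bp) from the
    # published design table; honeycomb packing assumed.
    "6HB": lambda: build_bundle(6, "honeycomb", 428.0, 2.0, 0.5, name="6HB"),
    "10HB": lambda: build_bundle(10, "honeycomb", 257.0, 2.0, 0.5, name="10HB"),
}

PRESET_NAMES = tuple(_PRESET_BUILDERS)


def preset(name: str) -> NanobeamDesign:
    """Return a named preset design (C85L/C85N/C170L/C170N/6HB/10HB)."""
    try:
        return _PRESET_BUILDERS[name]()
    except KeyError:
        raise ValidationError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")
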