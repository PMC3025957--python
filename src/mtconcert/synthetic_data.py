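"""Forward simulator for mt genomes with a tandem duplication evolving under
per-generation gene conversion that spares a central tract (the putative
Replication Fork Barrier, RFB), plus slippage-heteroplasmic repeat arrays.

Model
-----
An ancestral circular genome is linearized and given a tandem duplication.
Inside the duplicated fragment a short central tract (the RFB) carries
ancestral divergence between the two copies: the tract escaped
homogenization long before the sampled radiation, so in real data paralogues
differ heavily there while orthologues stay similar. Each sampled individual
then evolves independently from this ancestor (star genealogy) for
``generations`` steps. Per generation and individual, events occur in a
fixed order: (1) substitutions in every segment at rate ``mu`` per site,
(2) small indels inside the RFB at rate ``indel_rate`` per copy, then
(3) with probability ``conversion_prob`` a gene-conversion event that
overwrites one copy's non-RFB portion with the other's (direction chosen at
random, both flanks in one event). The mutate-then-convert order means a
conversion event also erases same-generation mutations, so with
``conversion_prob = 1`` paralogue diversity outside the RFB is exactly zero.

Repeat arrays (control-region domain III analogue) are emulated as cloned
amplicons per individual: each clone's copy number performs a +/-1
unit random walk (slippage) clamped to ``copy_range``, and its units are
drawn from a fixed pool of unit-type variants with positional structure
(a beginning type, an end type, middle types, and a dedicated type for
single-unit arrays).

Every stochastic event is logged; replaying the log over the ancestor
reconstructs every emitted sequence byte-for-byte (tested invariant).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import GenomeRecord

BASES = np.array(list("ACGT"))


@dataclass
class RepeatConfig:
    period: int = 113
    n_types: int = 6  # >= 4: one B, one E, one BE, rest M variants
    copy_range: tuple[int, int] = (1, 10)
    slip_prob: float = 0.08
    init_copies: int | None = None  # default: midpoint of copy_range

    def __post_init__(self) -> None:
        if self.copy_range[0] < 1:
            raise ValueError("copy_range minimum must be >= 1")
        if not 0 <= self.slip_prob <= 1:
            raise ValueError("slip_prob must be a probability")
        if self.n_types != 1 and self.n_types < 4:
            raise ValueError("n_types must be 1 (uniform array) or >= 4 (B, E, BE and >= 1 M)")
        if self.init_copies is None:
            self.init_copies = (self.copy_range[0] + self.copy_range[1]) // 2
        if not self.copy_range[0] <= self.init_copies <= self.copy_range[1]:
            raise ValueError("init_copies outside copy_range")


@dataclass
class SimConfig:
    seed: int = 0
    n_individuals: int = 6
    genome_len: int = 9000  # ancestral length before duplication
    dup: tuple[int, int] = (3000, 1930)  # (start, length)
    rfb: tuple[int, int] = (1368, 159)  # (start, length) within the duplicate
    mu: float = 2.5e-4
    indel_rate: float = 0.01  # per generation per copy, events confined to the RFB
    generations: int = 40
    conversion_prob: float = 1.0
    rfb_divergence: float = 0.24  # ancestral per-site paralogue divergence inside the RFB
    repeat: RepeatConfig = field(default_factory=RepeatConfig)
    repeat_cr2: RepeatConfig | None = None  # CRII array; defaults derived from `repeat`
    second_repeat: RepeatConfig | None = None
    n_clones_per_individual: int = 6

    def __post_init__(self) -> None:
        ds, dl = self.dup
        rs, rl = self.rfb
        if not (0 <= rs and rs + rl <= dl):
            raise ValueError("rfb must be nested inside the duplicate")
        if ds < 0 or ds + dl > self.genome_len:
            raise ValueError("dup outside genome")
        for p in (self.mu, self.indel_rate, self.conversion_prob, self.rfb_divergence):
            if not 0 <= p <= 1:
                raise ValueError("rates/probabilities must lie in [0, 1]")
        if isinstance(self.repeat, tuple):
            self.repeat = RepeatConfig(*self.repeat)
        if self.repeat_cr2 is None:
            self.repeat_cr2 = RepeatConfig(
                period=self.repeat.period,
                n_types=self.repeat.n_types,
                copy_range=(1, max(1, self.repeat.copy_range[1] - 2)),
                slip_prob=self.repeat.slip_prob,
            )


@dataclass
class SimTruth:
    """Ground truth: ancestor, event log, RFB coordinates, repeat structure."""

    config: dict
    ancestor_segments: dict[str, str]  # flank1, I, II, flank2
    events: list[dict]
    genealogy_depth: dict[str, int]
    rfb_by_copy: dict[str, dict[str, tuple[int, int]]]  # individual -> copy -> copy coords
    rfb_genome_coords: dict[str, dict[str, tuple[int, int]]]
    copy_spans: dict[str, dict[str, tuple[int, int]]]
    clone_units: dict[str, list[str]]  # clone id -> ordered unit sequences
    clone_copy_number: dict[str, int]
    repeat_type_pool: dict[str, dict[str, str]]  # region -> role -> unit sequence

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


@dataclass
class SimResult:
    genomes: list[GenomeRecord]
    clones: list[GenomeRecord]
    truth: SimTruth


def _random_seq(rng: np.random.Generator, n: int, p=None) -> str:
    return "".join(rng.choice(BASES, size=n, p=p))


def _substitute(rng: np.random.Generator, base: str) -> str:
    others = [b for b in "ACGT" if b != base]
    return others[rng.integers(3)]


class _Individual:
    """Mutable per-lineage state: four segments plus the RFB interval per copy."""

    def __init__(self, name: str, segments: dict[str, str], rfb: tuple[int, int]):
        self.name = name
        self.seg = dict(segments)
        self.rfb = {"I": (rfb[0], rfb[0] + rfb[1]), "II": (rfb[0], rfb[0] + rfb[1])}

    def genome_seq(self) -> str:
        return self.seg["flank1"] + self.seg["I"] + self.seg["II"] + self.seg["flank2"]


def _apply_event(ind: _Individual, ev: dict) -> None:
    """Apply one logged event; used both by the simulator and by replay."""
    kind = ev["type"]
    if kind == "sub":
        seg = ind.seg[ev["segment"]]
        pos = ev["pos"]
        assert seg[pos] == ev["from"]
        ind.seg[ev["segment"]] = seg[:pos] + ev["to"] + seg[pos + 1 :]
    elif kind == "ins":
        cp = ev["segment"]
        seg = ind.seg[cp]
        pos = ev["pos"]
        ind.seg[cp] = seg[:pos] + ev["insert"] + seg[pos:]
        s, e = ind.rfb[cp]
        ind.rfb[cp] = (s, e + len(ev["insert"]))
    elif kind == "del":
        cp = ev["segment"]
        seg = ind.seg[cp]
        pos, n = ev["pos"], ev["size"]
        assert seg[pos : pos + n] == ev["deleted"]
        ind.seg[cp] = seg[:pos] + seg[pos + n :]
        s, e = ind.rfb[cp]
        ind.rfb[cp] = (s, e - n)
    elif kind == "conv":
        donor, recip = ev["donor"], ev["recipient"]
        ds, de = ind.rfb[donor]
        rs, re = ind.rfb[recip]
        dseq, rseq = ind.seg[donor], ind.seg[recip]
        ind.seg[recip] = dseq[:ds] + rseq[rs:re] + dseq[de:]
        ind.rfb[recip] = (ds, ds + (re - rs))
    else:  # pragma: no cover
        raise ValueError(f"unknown event type {kind!r}")


def _evolve_generation(
    rng: np.random.Generator, ind: _Individual, cfg: SimConfig, gen: int, events: list[dict]
) -> None:
    # 1) substitutions, every segment independently
    for segname in ("flank1", "I", "II", "flank2"):
        seg = ind.seg[segname]
        n_mut = rng.binomial(len(seg), cfg.mu)
        if n_mut:
            for pos in sorted(rng.choice(len(seg), size=n_mut, replace=False)):
                ev = {
                    "type": "sub",
                    "gen": gen,
                    "individual": ind.name,
                    "segment": segname,
                    "pos": int(pos),
                    "from": ind.seg[segname][pos],
                    "to": _substitute(rng, ind.seg[segname][pos]),
                }
                _apply_event(ind, ev)
                events.append(ev)
    # 2) small indels confined to the RFB tract
    for cp in ("I", "II"):
        if rng.random() < cfg.indel_rate:
            s, e = ind.rfb[cp]
            size = int(rng.integers(1, 4))
            if e - s < size + 2:
                continue  # tract too short for an event of this size
            if rng.random() < 0.5:  # deletion
                pos = int(rng.integers(s, e - size))
                ev = {
                    "type": "del",
                    "gen": gen,
                    "individual": ind.name,
                    "segment": cp,
                    "pos": pos,
                    "size": size,
                    "deleted": ind.seg[cp][pos : pos + size],
                }
            else:  # slippage-like insertion duplicating adjacent bases
                pos = int(rng.integers(s, e - size))
                ev = {
                    "type": "ins",
                    "gen": gen,
                    "individual": ind.name,
                    "segment": cp,
                    "pos": pos,
                    "insert": ind.seg[cp][pos : pos + size],
                }
            _apply_event(ind, ev)
            events.append(ev)
    # 3) whole-tract gene conversion sparing the RFB
    if rng.random() < cfg.conversion_prob:
        donor = "I" if rng.random() < 0.5 else "II"
        recip = "II" if donor == "I" else "I"
        ev = {"type": "conv", "gen": gen, "individual": ind.name, "donor": donor, "recipient": recip}
        rfb_before = ind.seg[recip][ind.rfb[recip][0] : ind.rfb[recip][1]]
        _apply_event(ind, ev)
        rfb_after = ind.seg[recip][ind.rfb[recip][0] : ind.rfb[recip][1]]
        assert rfb_after == rfb_before, "conversion must never alter the RFB tract"
        events.append(ev)


def _a_rich_unit(rng: np.random.Generator, period: int) -> str:
    """A unit with the heavy-strand composition of avian CR repeats: 47% A, G-poor."""
    n_a = round(0.47 * period)
    n_g = max(1, round(0.06 * period))
    rest = period - n_a - n_g
    letters = list("A" * n_a + "G" * n_g + "C" * (rest // 2) + "T" * (rest - rest // 2))
    rng.shuffle(letters)
    return "".join(letters)


def _make_type_pool(
    rng: np.random.Generator, rep: RepeatConfig, base_seq: str | None = None
) -> dict[str, str]:
    """Unit-type variants with positional roles: B, E, BE and M1..Mk.

    Variants differ from a base unit by a couple of substitutions; all types
    of a region share the unit length (the length spread real types can show
    is not emulated — see the methods note).
    """
    base = base_seq if base_seq is not None else _random_seq(rng, rep.period)
    if rep.n_types == 1:
        return {"ALL": base}
    roles = ["B", "E", "BE"] + [f"M{i + 1}" for i in range(rep.n_types - 3)]
    pool: dict[str, str] = {}
    for role in roles:
        unit = list(base)
        for pos in rng.choice(rep.period, size=min(2, rep.period), replace=False):
            unit[pos] = _substitute(rng, unit[pos])
        pool[role] = "".join(unit)
    # ensure all types are distinct sequences
    seen: set[str] = set()
    for role, seq in pool.items():
        while seq in seen:
            pos = int(rng.integers(len(seq)))
            seq = seq[:pos] + _substitute(rng, seq[pos]) + seq[pos + 1 :]
        pool[role] = seq
        seen.add(seq)
    return pool


def _compose_array(rng: np.random.Generator, pool: dict[str, str], k: int) -> list[str]:
    if "ALL" in pool:
        return [pool["ALL"]] * k
    if k == 1:
        return [pool["BE"]]
    mids = [r for r in pool if r.startswith("M")]
    middle = [pool[mids[rng.integers(len(mids))]] for _ in range(k - 2)]
    return [pool["B"], *middle, pool["E"]]


def _slip_walk(rng: np.random.Generator, rep: RepeatConfig, steps: int) -> int:
    k = rep.init_copies
    lo, hi = rep.copy_range
    for _ in range(steps):
        if rng.random() < rep.slip_prob:
            k += 1 if rng.random() < 0.5 else -1
            k = min(max(k, lo), hi)
    return k


def simulate_dataset(cfg: SimConfig) -> SimResult:
    """Run the full simulation; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    anc = _random_seq(rng, cfg.genome_len)
    ds, dl = cfg.dup
    dup_seg = anc[ds : ds + dl]
    rs, rl = cfg.rfb
    # ancestral paralogue divergence confined to the RFB tract of copy II
    copy2 = list(dup_seg)
    n_div = 0
    for pos in range(rs, rs + rl):
        if rng.random() < cfg.rfb_divergence:
            copy2[pos] = _substitute(rng, copy2[pos])
            n_div += 1
    segments = {
        "flank1": anc[:ds],
        "I": dup_seg,
        "II": "".join(copy2),
        "flank2": anc[ds + dl :],
    }

    events: list[dict] = []
    individuals = [_Individual(f"sim-{i + 1}", segments, (rs, rl)) for i in range(cfg.n_individuals)]
    for gen in range(1, cfg.generations + 1):
        for ind in individuals:
            _evolve_generation(rng, ind, cfg, gen, events)

    genomes = [GenomeRecord(id=ind.name, seq=ind.genome_seq(), circular=True) for ind in individuals]

    # repeat-array clones
    pools = {"CRI": _make_type_pool(rng, cfg.repeat)}
    pools["CRII"] = pools["CRI"]  # same unit types occur in both CRs
    region_cfgs = {"CRI": cfg.repeat, "CRII": cfg.repeat_cr2}
    if cfg.second_repeat is not None:
        pools["second_repeat"] = _make_type_pool(
            rng, cfg.second_repeat, base_seq=_a_rich_unit(rng, cfg.second_repeat.period)
        )
        region_cfgs["second_repeat"] = cfg.second_repeat
    clones: list[GenomeRecord] = []
    clone_units: dict[str, list[str]] = {}
    clone_cn: dict[str, int] = {}
    for ind in individuals:
        for region, rep in region_cfgs.items():
            for c in range(cfg.n_clones_per_individual):
                k = _slip_walk(rng, rep, cfg.generations)
                units = _compose_array(rng, pools[region], k)
                cid = f"{ind.name}_c{c + 1}:{region}"
                clones.append(GenomeRecord(id=cid, seq="".join(units)))
                clone_units[cid] = units
                clone_cn[cid] = k

    len_f1 = len(segments["flank1"])
    copy_spans: dict[str, dict[str, tuple[int, int]]] = {}
    rfb_by_copy: dict[str, dict[str, tuple[int, int]]] = {}
    rfb_genome: dict[str, dict[str, tuple[int, int]]] = {}
    for ind in individuals:
        l1, l2 = len(ind.seg["I"]), len(ind.seg["II"])
        copy_spans[ind.name] = {"I": (len_f1, len_f1 + l1), "II": (len_f1 + l1, len_f1 + l1 + l2)}
        rfb_by_copy[ind.name] = dict(ind.rfb)
        rfb_genome[ind.name] = {
            cp: (copy_spans[ind.name][cp][0] + ind.rfb[cp][0], copy_spans[ind.name][cp][0] + ind.rfb[cp][1])
            for cp in ("I", "II")
        }

    cfg_dict = asdict(cfg)
    truth = SimTruth(
        config=cfg_dict,
        ancestor_segments=segments,
        events=events,
        genealogy_depth={ind.name: cfg.generations for ind in individuals},
        rfb_by_copy=rfb_by_copy,
        rfb_genome_coords=rfb_genome,
        copy_spans=copy_spans,
        clone_units=clone_units,
        clone_copy_number=clone_cn,
        repeat_type_pool=pools,
    )
    return SimResult(genomes=genomes, clones=clones, truth=truth)


def replay_events(truth: SimTruth) -> dict[str, str]:
    """Reconstruct every individual's genome from the ancestor + event log."""
    cfg = truth.config
    rs, rl = cfg["rfb"]
    inds = {
        name: _Individual(name, truth.ancestor_segments, (rs, rl))
        for name in (f"sim-{i + 1}" for i in range(cfg["n_individuals"]))
    }
    for ev in truth.events:
        _apply_event(inds[ev["individual"]], ev)
    return {name: ind.genome_seq() for name, ind in inds.items()}


def default_scenario(seed: int = 1) -> SimConfig:
    """The hornbill-like study geometry: 6 individuals, a ~1,930 bp duplicate
    with a 159 bp RFB tract placed after 1,368 bp, a 113 bp repeat with copy
    numbers 1-10 (typical 9), and a second 34 bp A-rich repeat."""
    return SimConfig(
        seed=seed,
        n_individuals=6,
        genome_len=9000,
        dup=(3000, 1930),
        rfb=(1368, 159),
        mu=2.5e-4,
        generations=40,
        conversion_prob=1.0,
        rfb_divergence=0.24,
        repeat=RepeatConfig(period=113, n_types=6, copy_range=(1, 10), slip_prob=0.05, init_copies=9),
        repeat_cr2=RepeatConfig(period=113, n_types=6, copy_range=(1, 8), slip_prob=0.05, init_copies=6),
        second_repeat=RepeatConfig(
            period=34, n_types=1, copy_range=(1, 27), slip_prob=0.05, init_copies=9
        ),
        n_clones_per_individual=6,
    )


def write_dataset(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write genomes FASTA, clones FASTA and truth JSON to a directory."""
    from .genome_io import write_genomes

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genomes": outdir / "genomes.fasta",
        "clones": outdir / "clones.fasta",
        "truth": outdir / "truth.json",
    }
    write_genomes(result.genomes, paths["genomes"])
    write_genomes(result.clones, paths["clones"])
    result.truth.to_json(paths["truth"])
    return paths
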