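"""Sequencing-channel simulator for composite-letter pools.

Models the write-and-read channel in three stages:

1. **Copy counts** — the number of reads per designed strand is drawn from a
   negative binomial (Poisson-Gamma) distribution with mean ``coverage_mean``
   and shape ``dispersion``, capturing PCR amplification bias on top of
   Poisson sampling.  ``dispersion = inf`` gives the pure Poisson limit.
2. **Instantiation** — each composite position of every copy is realised as a
   single natural base drawn from the letter's composition vector sigma;
   natural positions are copied verbatim.
3. **Errors** — each position independently suffers a substitution
   (probability ``p_sub``, uniform over the other three bases), a deletion
   (``p_del``) or an insertion of a uniform base after it (``p_ins``), so the
   expected number of events in a k-nt read is ``k * (p_ins + p_del + p_sub)``.

Optional strand breakage truncates a read at a uniform point strictly between
the two primers (keeping either side with equal probability), an in-silico
analogue of thermal degradation: every broken read retains exactly one intact
primer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .constellation import BASES, IUPAC_COMPOSITION, letter_sigma
from .mapping import StrandFrame

__all__ = [
    "ChannelParams",
    "SimulatedPool",
    "CopyFit",
    "sample_copy_counts",
    "fit_copy_distribution",
    "instantiate_strand",
    "inject_errors",
    "simulate_pool",
    "METHODS_ERROR_PRESET",
]

#: Default per-position error rates used throughout the simulation studies.
METHODS_ERROR_PRESET = dict(p_ins=0.001, p_del=0.001, p_sub=0.002)

_BASE_ARR = np.frombuffer("ATGC".encode(), dtype=np.uint8)
_BASE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ATGC"):
    _BASE_LUT[ord(_b)] = _i
_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


@dataclass(frozen=True)
class ChannelParams:
    """Channel configuration; all probabilities are per nucleotide position."""

    p_ins: float = 0.001
    p_del: float = 0.001
    p_sub: float = 0.002
    coverage_mean: float = 30.0
    dispersion: float = 4.0  # negative-binomial shape r; inf -> Poisson
    seed: int = 0
    paired_end: bool = False
    read_length: int = 150
    break_rate: float = 0.0

    def __post_init__(self):
        p_err = self.p_ins + self.p_del + self.p_sub
        if not (0 <= self.p_ins < 1 and 0 <= self.p_del < 1 and 0 <= self.p_sub < 1 and p_err < 1):
            raise ValueError("error probabilities must lie in [0,1) with sum < 1")
        if self.coverage_mean <= 0 or self.dispersion <= 0:
            raise ValueError("coverage_mean and dispersion must be positive")
        if not 0 <= self.break_rate < 1:
            raise ValueError("break_rate must lie in [0,1)")

    @property
    def p_error(self) -> float:
        return self.p_ins + self.p_del + self.p_sub


def sample_copy_counts(
    n_strands: int, params: ChannelParams, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Per-strand read counts: NB(mean=M, shape=r), or Poisson when r = inf."""
    if n_strands < 1:
        raise ValueError("n_strands must be >= 1")
    rng = np.random.default_rng(params.seed) if rng is None else rng
    M, r = params.coverage_mean, params.dispersion
    if math.isinf(r):
        return rng.poisson(M, size=n_strands)
    p = r / (r + M)
    return rng.negative_binomial(r, p, size=n_strands)


@dataclass(frozen=True)
class CopyFit:
    """Maximum-likelihood negative-binomial fit of observed copy counts."""

    r: float
    p: float
    mean: float
    poisson_fallback: bool


def fit_copy_distribution(counts) -> CopyFit:
    """Fit NB(r, p) to read counts by profile maximum likelihood.

    The NB mean MLE equals the sample mean, so only the shape ``r`` is
    optimised.  When the sample variance does not exceed the mean there is no
    over-dispersion to fit and a Poisson fallback is reported (r = inf).
    """
    x = np.asarray(counts, dtype=float)
    if len(x) < 100:
        raise ValueError("need at least 100 observations")
    mean = float(x.mean())
    var = float(x.var())
    if var <= mean or mean == 0:
        return CopyFit(math.inf, 0.0, mean, True)

    def nll(log_r: float) -> float:
        r = math.exp(log_r)
        return -stats.nbinom.logpmf(x, r, r / (r + mean)).sum()

    # moment estimate r = mean^2/(var-mean) seeds the search
    r0 = max(mean * mean / (var - mean), 1e-3)
    res = optimize.minimize_scalar(
        nll, bracket=(math.log(r0) - 2, math.log(r0), math.log(r0) + 2)
    )
    r = float(math.exp(res.x))
    return CopyFit(r, r / (r + mean), mean, False)


def instantiate_strand(
    frame: StrandFrame,
    rng: np.random.Generator | None = None,
    epsilon: float = 0.0,
) -> str:
    """Realise one molecule of a composite strand as natural bases."""
    rng = np.random.default_rng() if rng is None else rng
    out = []
    for ch in frame.sequence:
        comp = IUPAC_COMPOSITION[ch]
        if len(comp) == 1:
            out.append(comp)
        else:
            sigma = letter_sigma(ch, epsilon)
            out.append(BASES[rng.choice(4, p=sigma)])
    return "".join(out)


def inject_errors(
    seq: str, params: ChannelParams, rng: np.random.Generator | None = None
) -> tuple[str, list[tuple[int, str, str]]]:
    """Apply per-position substitution/deletion/insertion errors.

    At each position exactly one of {sub, del, ins, none} occurs, with
    probabilities (p_sub, p_del, p_ins, rest).  Returns the corrupted
    sequence and an event log of ``(position, kind, base)`` tuples.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    arr = _BASE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr < 0).any():
        raise ValueError("inject_errors expects a natural-base (ATGC) sequence")
    u = rng.random(len(seq))
    t_sub = params.p_sub
    t_del = t_sub + params.p_del
    t_ins = t_del + params.p_ins
    sub_pos = np.nonzero(u < t_sub)[0]
    del_pos = np.nonzero((u >= t_sub) & (u < t_del))[0]
    ins_pos = np.nonzero((u >= t_del) & (u < t_ins))[0]

    out = arr.copy()
    out[sub_pos] = (out[sub_pos] + 1 + rng.integers(0, 3, size=len(sub_pos))) % 4
    ins_bases = rng.integers(0, 4, size=len(ins_pos))

    events: list[tuple[int, str, str]] = []
    for i in sub_pos:
        events.append((int(i), "sub", BASES[out[i]]))
    for i in del_pos:
        events.append((int(i), "del", seq[i]))
    for i, b in zip(ins_pos, ins_bases):
        events.append((int(i), "ins", BASES[b]))
    events.sort()

    if len(del_pos) == 0 and len(ins_pos) == 0:
        return _BASE_ARR[out].tobytes().decode(), events
    keep = np.ones(len(seq), dtype=bool)
    keep[del_pos] = False
    pieces: list[str] = []
    prev = 0
    insert_at = dict(zip(ins_pos.tolist(), ins_bases.tolist()))
    bytes_out = _BASE_ARR[out]
    for i in sorted(insert_at):
        seg = bytes_out[prev : i + 1][keep[prev : i + 1]]
        pieces.append(seg.tobytes().decode())
        pieces.append(BASES[insert_at[i]])
        prev = i + 1
    seg = bytes_out[prev:][keep[prev:]]
    pieces.append(seg.tobytes().decode())
    return "".join(pieces), events


@dataclass
class SimulatedPool:
    """Reads plus ground truth emitted by :func:`simulate_pool`."""

    reads: list  # str, or (r1, r2) tuples in paired-end mode
    addresses: np.ndarray  # true source address per read
    copy_counts: np.ndarray  # per-strand draw, index = strand order in frames
    n_sub: np.ndarray = field(default=None)
    n_del: np.ndarray = field(default=None)
    n_ins: np.ndarray = field(default=None)
    broken: np.ndarray = field(default=None)

    def __post_init__(self):
        assert len(self.reads) == len(self.addresses) == int(self.copy_counts.sum())

    def write_fastq(self, path, truth_path=None) -> None:
        """Write reads as FASTQ (constant placeholder qualities) + truth TSV."""
        with open(path, "w") as fh:
            for i, read in enumerate(self.reads):
                seq = read if isinstance(read, str) else read[0]
                fh.write(f"@read{i} addr={self.addresses[i]}\n{seq}\n+\n{'I' * len(seq)}\n")
        if truth_path is not None:
            with open(truth_path, "w") as fh:
                fh.write("read_id\taddress\tn_sub\tn_del\tn_ins\tbroken\n")
                for i in range(len(self.reads)):
                    fh.write(
                        f"read{i}\t{self.addresses[i]}\t{self.n_sub[i]}\t"
                        f"{self.n_del[i]}\t{self.n_ins[i]}\t{int(self.broken[i])}\n"
                    )


def _frames_letter_ids(frames: list[StrandFrame]) -> np.ndarray:
    """(n_strands, L) matrix of IUPAC letter ids (index into the 15-code table)."""
    codes = list(IUPAC_COMPOSITION)
    lut = np.full(256, -1, dtype=np.int8)
    for i, c in enumerate(codes):
        lut[ord(c)] = i
    seqs = "".join(f.sequence for f in frames)
    arr = lut[np.frombuffer(seqs.encode(), dtype=np.uint8)]
    if (arr < 0).any():
        raise ValueError("frame contains a non-IUPAC character")
    return arr.reshape(len(frames), -1)


def simulate_pool(frames: list[StrandFrame], params: ChannelParams) -> SimulatedPool:
    """Simulate sequencing of a pool of composite strands.

    Fully vectorised: copies are drawn per strand, composite positions are
    instantiated from their sigma vectors, and error events are applied per
    position.  Reads containing indels (a minority at realistic rates) are
    reassembled individually.  Deterministic for a given ``params.seed``.
    """
    if not frames:
        raise ValueError("frames must be non-empty")
    lens = {len(f) for f in frames}
    if len(lens) != 1:
        raise ValueError("all frames must have equal length")
    L = lens.pop()
    rng = np.random.default_rng(params.seed)
    counts = sample_copy_counts(len(frames), params, rng)
    n_reads = int(counts.sum())
    strand_of_read = np.repeat(np.arange(len(frames)), counts)
    addresses = np.array([f.address for f in frames])[strand_of_read]

    letter_ids = _frames_letter_ids(frames)
    # cumulative sigma thresholds per letter id for inverse-CDF sampling
    codes = list(IUPAC_COMPOSITION)
    cdf = np.cumsum(np.stack([letter_sigma(c) for c in codes]), axis=1)[:, :3]

    p5 = frames[0].primer5
    p3 = frames[0].primer3
    interior_lo = len(p5)
    interior_hi = L - len(p3)

    reads: list = [None] * n_reads
    n_sub = np.zeros(n_reads, dtype=np.int32)
    n_del = np.zeros(n_reads, dtype=np.int32)
    n_ins = np.zeros(n_reads, dtype=np.int32)
    broken = np.zeros(n_reads, dtype=bool)

    t_sub = params.p_sub
    t_del = t_sub + params.p_del
    t_ins = t_del + params.p_ins

    chunk = max(1, 40_000_000 // max(L, 1))
    for lo in range(0, n_reads, chunk):
        hi = min(lo + chunk, n_reads)
        ids = letter_ids[strand_of_read[lo:hi]]  # (c, L)
        u = rng.random(ids.shape)
        bases = (u[:, :, None] > cdf[ids]).sum(axis=2).astype(np.uint8)  # 0..3
        ue = rng.random(ids.shape)
        sub_mask = ue < t_sub
        if sub_mask.any():
            shift = rng.integers(1, 4, size=int(sub_mask.sum()))
            bases[sub_mask] = (bases[sub_mask] + shift) % 4
        n_sub[lo:hi] = sub_mask.sum(axis=1)
        del_mask = (ue >= t_sub) & (ue < t_del)
        ins_mask = (ue >= t_del) & (ue < t_ins)
        n_del[lo:hi] = del_mask.sum(axis=1)
        n_ins[lo:hi] = ins_mask.sum(axis=1)
        byte_rows = _BASE_ARR[bases]

        indel_rows = np.nonzero(del_mask.any(axis=1) | ins_mask.any(axis=1))[0]
        clean = np.ones(hi - lo, dtype=bool)
        clean[indel_rows] = False
        for row in np.nonzero(clean)[0]:
            reads[lo + row] = byte_rows[row].tobytes().decode()
        for row in indel_rows:
            pieces = []
            dm, im = del_mask[row], ins_mask[row]
            rowbytes = byte_rows[row]
            ins_pos = np.nonzero(im)[0]
            ins_bases = _BASE_ARR[rng.integers(0, 4, size=len(ins_pos))]
            ins_iter = dict(zip(ins_pos.tolist(), ins_bases.tolist()))
            for i in range(L):
                if not dm[i]:
                    pieces.append(rowbytes[i])
                if i in ins_iter:
                    pieces.append(ins_iter[i])
            reads[lo + row] = bytes(pieces).decode()

    if params.break_rate > 0 and interior_hi - interior_lo > 1:
        u = rng.random(n_reads)
        to_break = np.nonzero(u < params.break_rate)[0]
        points = rng.integers(interior_lo + 1, interior_hi, size=len(to_break))
        keep5 = rng.random(len(to_break)) < 0.5
        for idx, pt, k5 in zip(to_break, points, keep5):
            s = reads[idx]
            # breakpoint expressed on the designed coordinate; clamp to the
            # realised read length (indels may have shifted it slightly)
            pt = min(int(pt), max(len(s) - 1, 1))
            reads[idx] = s[:pt] if k5 else s[pt:]
            broken[idx] = True

    if params.paired_end:
        rl = params.read_length
        reads = [(s[:rl], revcomp(s)[:rl]) for s in reads]

    return SimulatedPool(reads, addresses, counts, n_sub, n_del, n_ins, broken)
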