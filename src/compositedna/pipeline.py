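"""End-to-end encode and readout for composite-letter DNA storage.

Write path: bytes -> bit stream -> RS codewords (per block, symbol-interleaved)
-> composite letters -> 60-letter payloads framed with double-end indices and
primers.

Read path, mirroring the recovery procedure step by step: merge paired reads
-> locate both primers (substitution-only Hamming scan) -> discard reads whose
extracted region is not exactly the designed length (indel filter) -> decode
the double-end indices and group payload copies into per-strand pileups ->
composite-letter detection (SP / MAP / KL) -> letters back to bits with
erasure propagation -> de-interleave -> RS errors-and-erasures decoding ->
strip padding -> bytes.

Strands with no usable reads become erased symbols, not wrong symbols; the RS
budget ``2*errors + erasures <= n - k`` then decides recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .channel_sim import ChannelParams, SimulatedPool, revcomp, simulate_pool
from .constellation import Alphabet
from .detection import _detect_counts
from .ecc import Interleaver, RSCode, RSDecodeFailure
from .index_coding import DoubleEndIndexCodec, IndexReject, WideIndexCodec
from .mapping import (
    CodeConfig,
    FramingError,
    StrandFrame,
    bits_to_letters,
    build_frames,
    frame_stats,
    letters_to_bits,
)

__all__ = [
    "EncodeInfo",
    "RecoveryReport",
    "default_index_codec",
    "encode_bytes",
    "merge_pairs",
    "locate_primers",
    "length_filter",
    "group_reads",
    "decode_pool",
    "coverage_sweep",
    "write_reference_fasta",
    "read_fastq",
]

_BASE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ATGC"):
    _BASE_LUT[ord(_b)] = _i


def default_index_codec(config: CodeConfig):
    """Pick the index codec implied by a configuration's index lengths."""
    if config.index_len_5p == config.index_len_3p == 8 and config.strand_count <= 126:
        return DoubleEndIndexCodec()
    address_bits = max(8, int(math.ceil(math.log2(config.strand_count + 1))))
    return WideIndexCodec(index_len=config.index_len_5p, address_bits=address_bits)


# ---------------------------------------------------------------------------
# encode
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EncodeInfo:
    """Sidecar metadata needed to invert an encoding."""

    config: CodeConfig
    file_bytes: int
    pad_bits: int
    interleaver_seed: int

    def to_yaml(self) -> str:
        import yaml

        c = self.config
        return yaml.safe_dump(
            {
                "preset": c.name,
                "alphabet": c.alphabet.name,
                "rs_n": c.rs_n,
                "rs_k": c.rs_k,
                "field_bits": c.field_bits,
                "n_blocks": c.n_blocks,
                "payload_letters": c.payload_letters,
                "index_len_5p": c.index_len_5p,
                "index_len_3p": c.index_len_3p,
                "primer_5p": c.primer_5p,
                "primer_3p": c.primer_3p,
                "ecc": c.ecc,
                "file_bytes": self.file_bytes,
                "pad_bits": self.pad_bits,
                "interleaver_seed": self.interleaver_seed,
            }
        )


def _block_interleavers(config: CodeConfig) -> list[Interleaver]:
    return [
        Interleaver(config.rs_n, config.interleaver_seed + b)
        for b in range(config.n_blocks)
    ]


def encode_bytes(
    data: bytes, config: CodeConfig, index_codec=None
) -> tuple[list[StrandFrame], EncodeInfo]:
    """Encode a byte string into addressed composite strand frames."""
    if config.ecc != "rs":
        raise NotImplementedError(
            f"outer code {config.ecc!r} has layout support only; encoding "
            "requires an RS preset or an external codec plug-in"
        )
    stats = frame_stats(config, len(data))  # raises CapacityError when too big
    m = config.field_bits
    if m % config.alphabet.bits_per_group and config.alphabet.bits_per_group % m:
        raise ValueError("symbol size incompatible with letter group size")
    index_codec = index_codec or default_index_codec(config)

    bits = np.unpackbits(np.frombuffer(data, dtype=np.uint8))
    total_bits = config.n_blocks * config.rs_k * m
    pad = total_bits - len(bits)
    bits = np.concatenate([bits, np.zeros(pad, dtype=np.uint8)])
    weights = (1 << np.arange(m - 1, -1, -1)).astype(np.int64)
    msg_symbols = (bits.reshape(-1, m) @ weights).reshape(config.n_blocks, config.rs_k)

    rs = RSCode(config.rs_n, config.rs_k, m)
    ils = _block_interleavers(config)
    cw_symbols = np.empty((config.n_blocks, config.rs_n), dtype=np.int64)
    for b in range(config.n_blocks):
        cw_symbols[b] = ils[b].interleave(rs.encode(msg_symbols[b]))

    shifts = np.arange(m - 1, -1, -1)
    cw_bits = ((cw_symbols.reshape(-1)[:, None] >> shifts[None, :]) & 1).astype(np.uint8)
    letters, extra_pad = bits_to_letters(cw_bits.reshape(-1), config.alphabet)
    assert extra_pad == 0, "config geometry must tile bits exactly"
    frames = build_frames(letters, config, index_codec)
    assert len(frames) == stats.strand_count
    return frames, EncodeInfo(config, len(data), pad, config.interleaver_seed)


def write_reference_fasta(frames: Sequence[StrandFrame], path) -> None:
    """Composite reference strands as IUPAC FASTA; record id = padded address."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    width = len(str(frames[-1].address)) if frames else 1
    records = [
        SeqRecord(Seq(f.sequence), id=str(f.address).zfill(width), description="")
        for f in frames
    ]
    seqio_write(records, str(path), "fasta")


def read_fastq(path, paired_with=None):
    """Read FASTQ into read strings (or (r1, r2) tuples when paired)."""
    from Bio.SeqIO import parse

    r1 = [str(rec.seq) for rec in parse(str(path), "fastq")]
    if paired_with is None:
        return r1
    r2 = [str(rec.seq) for rec in parse(str(paired_with), "fastq")]
    if len(r1) != len(r2):
        raise ValueError("paired FASTQ files differ in read count")
    return list(zip(r1, r2))


# ---------------------------------------------------------------------------
# read processing
# ---------------------------------------------------------------------------

def merge_pairs(
    r1: str,
    r2: str | None,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.10,
) -> str | None:
    """Overlap-merge a read pair (R2 is reverse-complemented first).

    Scans overlaps from longest to shortest, accepting the first with at most
    ``max_mismatch_frac`` mismatches; R1 wins base conflicts.  Returns the
    merged sequence or None when no acceptable overlap exists.  A single read
    (``r2 is None``) passes through unchanged.
    """
    if r2 is None:
        return r1
    rc2 = revcomp(r2)
    a = np.frombuffer(r1.encode(), dtype=np.uint8)
    b = np.frombuffer(rc2.encode(), dtype=np.uint8)
    for ov in range(min(len(a), len(b)), min_overlap - 1, -1):
        mism = int((a[len(a) - ov :] != b[:ov]).sum())
        if mism <= max_mismatch_frac * ov:
            return r1 + rc2[ov:]
    return None


def _hamming_at(seq: np.ndarray, probe: np.ndarray, offset: int) -> int:
    if offset < 0 or offset + len(probe) > len(seq):
        return len(probe) + 1
    return int((seq[offset : offset + len(probe)] != probe).sum())


def locate_primers(
    seq: str,
    primer5: str,
    primer3: str,
    max_mismatch: int = 2,
    window: int = 4,
    try_revcomp: bool = True,
) -> str | None:
    """Extract the index+payload interior of a read by primer alignment.

    Substitution-only Hamming matching: each primer is sought first within
    ``window`` nt of its expected position (primer5 at the start, primer3
    ending at the read end), then by a global scan.  Reads containing indels
    inside a primer are intentionally not recovered here; they die either at
    primer search or at the downstream exact-length filter.
    """
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    p5 = np.frombuffer(primer5.encode(), dtype=np.uint8)
    p3 = np.frombuffer(primer3.encode(), dtype=np.uint8)

    def find(probe: np.ndarray, expect: int) -> int | None:
        best = None
        for d in range(window + 1):
            for off in ({expect + d, expect - d} if d else {expect}):
                if _hamming_at(s, probe, off) <= max_mismatch:
                    return off
        for off in range(0, len(s) - len(probe) + 1):
            if _hamming_at(s, probe, off) <= max_mismatch:
                best = off
                break
        return best

    o5 = find(p5, 0)
    o3 = find(p3, len(s) - len(p3))
    if o5 is not None and o3 is not None and o3 > o5 + len(p5):
        return seq[o5 + len(p5) : o3]
    if try_revcomp:
        return locate_primers(
            revcomp(seq), primer5, primer3, max_mismatch, window, try_revcomp=False
        )
    return None


def length_filter(region: str, expected_length: int) -> bool:
    """Keep a retained region only when its length is exactly as designed."""
    return len(region) == expected_length


# ---------------------------------------------------------------------------
# grouping and pileups
# ---------------------------------------------------------------------------

@dataclass
class GroupingResult:
    pileups: np.ndarray  # (n_strands, payload_letters, 4)
    support: np.ndarray  # (n_strands,) accepted reads per strand
    status_counts: dict

    def pileup_table(self, alphabet: Alphabet | None = None) -> str:
        """TSV audit export: address, position, A/T/G/C counts."""
        lines = ["address\tposition\tA\tT\tG\tC"]
        for a in range(self.pileups.shape[0]):
            for i in range(self.pileups.shape[1]):
                c = self.pileups[a, i]
                lines.append(f"{a + 1}\t{i}\t{c[0]}\t{c[1]}\t{c[2]}\t{c[3]}")
        return "\n".join(lines) + "\n"


def group_reads(
    regions: Iterable[str],
    index_codec,
    n_strands: int,
    index_len_5p: int,
    index_len_3p: int,
    payload_letters: int,
) -> GroupingResult:
    """Decode double-end indices and aggregate payload copies into pileups.

    ``regions`` are already length-filtered interiors (index5|payload|index3).
    Reads whose ends disagree are tallied as crosstalk, other index failures
    as bad-index; neither contaminates a pileup.
    """
    exact = {}
    for a in range(1, n_strands + 1):
        i5, i3 = index_codec.encode(a)
        exact[i5 + i3] = a
    pile = np.zeros((n_strands, payload_letters, 4), dtype=np.int64)
    support = np.zeros(n_strands, dtype=np.int64)
    counts = {"kept": 0, "bad-index": 0, "crosstalk": 0}
    flat = []
    addr_list = []
    for region in regions:
        obs5 = region[:index_len_5p]
        obs3 = region[len(region) - index_len_3p :]
        addr = exact.get(obs5 + obs3)
        if addr is None:
            dec = index_codec.decode(obs5, obs3)
            if isinstance(dec, IndexReject):
                key = "crosstalk" if dec.reason == "end-mismatch" else "bad-index"
                counts[key] += 1
                continue
            if not 1 <= dec <= n_strands:
                counts["bad-index"] += 1
                continue
            addr = dec
        counts["kept"] += 1
        support[addr - 1] += 1
        flat.append(region[index_len_5p : index_len_5p + payload_letters])
        addr_list.append(addr - 1)
    if flat:
        payload = np.frombuffer("".join(flat).encode(), dtype=np.uint8)
        base = _BASE_LUT[payload].reshape(len(flat), -1)
        addrs = np.asarray(addr_list)
        # scatter-add via bincount on the combined (strand, position, base) key
        pos = np.arange(payload_letters)
        ok = base >= 0
        key = (
            addrs[:, None] * (payload_letters * 4)
            + pos[None, :] * 4
            + np.where(ok, base, 0)
        )[ok]
        pile = np.bincount(key, minlength=n_strands * payload_letters * 4).reshape(
            n_strands, payload_letters, 4
        )
    return GroupingResult(pile, support, counts)


# ---------------------------------------------------------------------------
# full decode
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Everything measured on the way from raw reads back to bytes."""

    total_reads: int
    status_counts: dict
    effective_read_fraction: float
    strand_dropout: int  # strands with zero accepted reads
    erasure_rate: float  # erased letter positions / total letter positions
    letter_error_rate: float | None  # vs truth frames, when provided
    symbol_erasures: int
    block_status: list
    success: bool
    detector: str
    seeds: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"reads                {self.total_reads}",
            f"effective fraction   {self.effective_read_fraction:.4f}",
            f"strand dropout       {self.strand_dropout}",
            f"erasure rate         {self.erasure_rate:.6f}",
        ]
        if self.letter_error_rate is not None:
            lines.append(f"letter error rate    {self.letter_error_rate:.6f}")
        lines.append(f"symbol erasures      {self.symbol_erasures}")
        lines.append(f"blocks ok            {sum(s == 'ok' for s in self.block_status)}"
                     f"/{len(self.block_status)}")
        lines.append(f"byte-exact success   {self.success}")
        return "\n".join(lines)


def _extract_regions(reads: list, config: CodeConfig, statuses: np.ndarray,
                     apply_length_filter: bool) -> list[tuple[int, str]]:
    """Primer location + length filter; returns (read index, region) pairs."""
    p5, p3 = config.primer_5p, config.primer_3p
    interior = config.index_len_5p + config.payload_letters + config.index_len_3p
    total = config.total_strand_length
    out: list[tuple[int, str]] = []

    full_idx = [i for i, s in enumerate(reads) if len(s) == total]
    rest_idx = [i for i, s in enumerate(reads) if len(s) != total]
    if full_idx:
        mat = np.frombuffer("".join(reads[i] for i in full_idx).encode(), np.uint8)
        mat = mat.reshape(len(full_idx), total)
        a5 = np.frombuffer(p5.encode(), np.uint8)
        a3 = np.frombuffer(p3.encode(), np.uint8)
        mm5 = (mat[:, : len(p5)] != a5[None, :]).sum(axis=1)
        mm3 = (mat[:, total - len(p3) :] != a3[None, :]).sum(axis=1)
        ok = (mm5 <= 2) & (mm3 <= 2)
        for row in np.nonzero(ok)[0]:
            i = full_idx[row]
            out.append((i, reads[i][len(p5) : total - len(p3)]))
            statuses[i] = 1
        rest_idx.extend(full_idx[row] for row in np.nonzero(~ok)[0])

    for i in rest_idx:
        region = locate_primers(reads[i], p5, p3)
        if region is None:
            statuses[i] = 2  # no-primer
        elif apply_length_filter and len(region) != interior:
            statuses[i] = 3  # bad-length
        else:
            if not apply_length_filter:
                region = region[:interior]
                if len(region) < config.index_len_5p + config.index_len_3p + 1:
                    statuses[i] = 3
                    continue
            statuses[i] = 1
            out.append((i, region))
    return out


def decode_pool(
    reads,
    config: CodeConfig,
    detector: str = "sp",
    index_codec=None,
    epsilon: float = 1e-6,
    apply_length_filter: bool = True,
    truth_frames: Sequence[StrandFrame] | None = None,
    file_bytes: int | None = None,
):
    """Run the full readout pipeline; returns ``(data | None, RecoveryReport)``.

    ``reads`` may be a :class:`SimulatedPool`, a list of merged read strings,
    a list of ``(r1, r2)`` pairs, or a FASTQ path.  ``file_bytes`` (from the
    encode sidecar) strips the zero padding; when omitted the full message
    capacity is returned.
    """
    if isinstance(reads, SimulatedPool):
        raw = reads.reads
    elif isinstance(reads, (str, bytes)) or hasattr(reads, "read"):
        raw = read_fastq(reads)
    else:
        raw = list(reads)
    merged: list[str] = []
    n_unmerged = 0
    for item in raw:
        if isinstance(item, tuple):
            m = merge_pairs(*item)
            if m is None:
                n_unmerged += 1
                continue
            merged.append(m)
        else:
            merged.append(item)

    index_codec = index_codec or default_index_codec(config)
    n_strands = config.strand_count
    # statuses: 0 pending, 1 kept-region, 2 no-primer, 3 bad-length
    statuses = np.zeros(len(merged), dtype=np.int8)
    regions = _extract_regions(merged, config, statuses, apply_length_filter)

    grouping = group_reads(
        (r for _, r in regions),
        index_codec,
        n_strands,
        config.index_len_5p,
        config.index_len_3p,
        config.payload_letters,
    )
    status_counts = {
        "unmerged": n_unmerged,
        "no-primer": int((statuses == 2).sum()),
        "bad-length": int((statuses == 3).sum()),
        "bad-index": grouping.status_counts["bad-index"],
        "crosstalk": grouping.status_counts["crosstalk"],
        "kept": grouping.status_counts["kept"],
    }
    total_reads = len(raw)

    # ---- detection (one vectorised call across all strand-positions) ----
    L = config.payload_letters
    flat_counts = grouping.pileups.reshape(n_strands * L, 4)
    det = _detect_counts(flat_counts, config.alphabet, detector, epsilon=epsilon)
    letters = det.letters.reshape(n_strands, L)

    letter_error_rate = None
    if truth_frames is not None:
        truth = np.frombuffer(
            "".join(f.payload for f in truth_frames).encode(), np.uint8
        ).reshape(n_strands, L)
        sym_lut = np.full(256, -9, dtype=np.int64)
        for i, sym in enumerate(config.alphabet.symbols):
            sym_lut[ord(sym)] = i
        truth_idx = sym_lut[truth]
        wrong = (letters >= 0) & (letters != truth_idx)
        letter_error_rate = float(wrong.sum() / letters.size)
    erasure_rate = float((letters < 0).sum() / letters.size)

    # ---- letters -> bits -> symbols with erasure propagation ----
    bits, group_erased = letters_to_bits(letters.reshape(-1), config.alphabet)
    m = config.field_bits
    weights = (1 << np.arange(m - 1, -1, -1)).astype(np.int64)
    symbols = bits.reshape(-1, m) @ weights
    groups_per_symbol = m // config.alphabet.bits_per_group
    sym_erased = group_erased.reshape(-1, groups_per_symbol).any(axis=1)
    symbols = symbols.reshape(config.n_blocks, config.rs_n)
    sym_erased = sym_erased.reshape(config.n_blocks, config.rs_n)

    rs = RSCode(config.rs_n, config.rs_k, m)
    ils = _block_interleavers(config)
    out_bits = []
    block_status = []
    success = True
    for b in range(config.n_blocks):
        received = ils[b].deinterleave(symbols[b])
        era = np.nonzero(ils[b].deinterleave(sym_erased[b]))[0]
        res = rs.decode(received, era)
        if isinstance(res, RSDecodeFailure):
            block_status.append(f"failed: {res.reason}")
            success = False
            out_bits.append(np.zeros(config.rs_k * m, dtype=np.uint8))
            continue
        msg, n_err, n_era = res
        block_status.append("ok")
        shifts = np.arange(m - 1, -1, -1)
        out_bits.append(((msg[:, None] >> shifts[None, :]) & 1).astype(np.uint8).reshape(-1))

    data = None
    if success:
        allbits = np.concatenate(out_bits)
        nbytes = file_bytes if file_bytes is not None else len(allbits) // 8
        data = np.packbits(allbits[: nbytes * 8]).tobytes()

    report = RecoveryReport(
        total_reads=total_reads,
        status_counts=status_counts,
        effective_read_fraction=status_counts["kept"] / max(total_reads, 1),
        strand_dropout=int((grouping.support == 0).sum()),
        erasure_rate=erasure_rate,
        letter_error_rate=letter_error_rate,
        symbol_erasures=int(sym_erased.sum()),
        block_status=block_status,
        success=success,
        detector=detector,
    )
    return data, report


# ---------------------------------------------------------------------------
# evaluation harness
# ---------------------------------------------------------------------------

def compare_detectors(
    frames: Sequence[StrandFrame],
    config: CodeConfig,
    channel: ChannelParams | None = None,
    seeds: Sequence[int] = (0,),
    epsilon_sp: float = 1e-6,
    epsilon_map: float | None = None,
):
    """Letter error rate and runtime of SP vs MAP vs KL on the same pools.

    The MAP comparator stands in for a noise-aware decoder and therefore
    defaults to channel-matched smoothing ``epsilon = p_sub / 3`` (the exact
    first-order emission probability of a foreign base under uniform 3-way
    substitution); SP and KL use the plain ``epsilon_sp``.  Returns a tidy
    DataFrame with one row per (seed, detector).
    """
    import time as _time

    import pandas as pd

    channel = channel or ChannelParams()
    if epsilon_map is None:
        epsilon_map = max(channel.p_sub / 3, 1e-6)
    alphabet = config.alphabet
    sym_lut = np.full(256, -9, dtype=np.int64)
    for i, s in enumerate(alphabet.symbols):
        sym_lut[ord(s)] = i
    truth = sym_lut[
        np.frombuffer("".join(f.payload for f in frames).encode(), np.uint8)
    ]
    rows = []
    for seed in seeds:
        pool = simulate_pool(list(frames), replace(channel, seed=int(seed)))
        statuses = np.zeros(len(pool.reads), dtype=np.int8)
        regions = _extract_regions(pool.reads, config, statuses, True)
        grouping = group_reads(
            (r for _, r in regions),
            default_index_codec(config),
            config.strand_count,
            config.index_len_5p,
            config.index_len_3p,
            config.payload_letters,
        )
        flat = grouping.pileups.reshape(-1, 4)
        for method, eps in (("sp", epsilon_sp), ("map", epsilon_map), ("kl", epsilon_sp)):
            t0 = _time.perf_counter()
            det = _detect_counts(flat, alphabet, method, epsilon=eps)
            dt = _time.perf_counter() - t0
            wrong = (det.letters >= 0) & (det.letters != truth)
            rows.append(
                dict(
                    seed=seed,
                    detector=method,
                    epsilon=eps,
                    letter_error_rate=float(wrong.mean()),
                    erasure_rate=float((det.letters < 0).mean()),
                    runtime_s=dt,
                )
            )
    return pd.DataFrame(rows)


def coverage_sweep(
    frames: Sequence[StrandFrame],
    config: CodeConfig,
    coverages: Sequence[float],
    n_trials: int = 1,
    seeds: Sequence[int] | None = None,
    detector: str = "sp",
    channel: ChannelParams | None = None,
    data: bytes | None = None,
    file_bytes: int | None = None,
):
    """Simulate -> decode over a coverage grid; returns a tidy DataFrame.

    ``seeds`` provides one seed per trial (defaults to 0..n_trials-1); each
    (coverage, trial) cell is an independent channel realisation.
    """
    import pandas as pd

    channel = channel or ChannelParams()
    seeds = list(seeds) if seeds is not None else list(range(n_trials))
    rows = []
    for cov in coverages:
        for t in range(n_trials):
            params = replace(channel, coverage_mean=float(cov), seed=int(seeds[t]))
            pool = simulate_pool(list(frames), params)
            out, rep = decode_pool(
                pool, config, detector=detector,
                truth_frames=frames, file_bytes=file_bytes,
            )
            ok = rep.success and (data is None or out == data)
            rows.append(
                dict(
                    coverage=cov,
                    trial=t,
                    seed=seeds[t],
                    success=bool(ok),
                    letter_error_rate=rep.letter_error_rate,
                    erasure_rate=rep.erasure_rate,
                    strand_dropout=rep.strand_dropout,
                    effective_read_fraction=rep.effective_read_fraction,
                )
            )
    return pd.DataFrame(rows)
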