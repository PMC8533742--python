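"""PSSM motif discovery, exact p-value scoring and promoter scanning.

The motif model is a position-specific scoring matrix (PSSM) of per-column
base probabilities, scanned as log-odds against a 0-order background.
Discovery is a MEME-style ZOOPS ("zero or one occurrence per sequence")
expectation-maximisation over both strands, optionally constrained to
palindromic (reverse-complement symmetric) matrices.  Match p-values are
exact tail probabilities of the log-odds score under the background model,
computed by column-wise convolution on a discretised score lattice.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import PromoterWindow, revcomp

ALPHABET = "ACGT"
_IDX = {b: i for i, b in enumerate(ALPHABET)}

IUPAC_CODES = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T", frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("GT"): "K", frozenset("AC"): "M", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V", frozenset("ACGT"): "N",
}
IUPAC_SETS = {code: bases for bases, code in IUPAC_CODES.items()}


def onehot(seq: str) -> np.ndarray:
    """(len, 4) one-hot encoding; N rows are all-zero."""
    arr = np.zeros((len(seq), 4))
    for i, b in enumerate(seq):
        j = _IDX.get(b)
        if j is not None:
            arr[i, j] = 1.0
    return arr


def background_from_sequences(sequences: list[str]) -> np.ndarray:
    """0-order base frequencies of a sequence set (N ignored)."""
    counts = np.zeros(4)
    for s in sequences:
        counts += onehot(s).sum(axis=0)
    if counts.sum() == 0:
        raise ValueError("no A/C/G/T bases in sequence set")
    return counts / counts.sum()


@dataclass
class PSSM:
    """Width-w base-probability matrix with a background model."""

    matrix: np.ndarray  # (w, 4) probabilities
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.25
    name: str = "motif"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must be (w, 4)")
        if np.any(self.matrix <= 0):
            raise ValueError("all matrix entries must be > 0")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("matrix columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """(w, 4) log2(p / background) score matrix (bits)."""
        return np.log2(self.matrix / self.background)

    def reverse_complement(self) -> "PSSM":
        return PSSM(
            self.matrix[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
            name=self.name + "_rc",
        )

    def information_content(self) -> float:
        """Total information content in bits relative to the background."""
        return float((self.matrix * self.log_odds()).sum())

    def sample_site(self, rng: np.random.Generator) -> str:
        cols = [rng.choice(4, p=col) for col in self.matrix]
        return "".join(ALPHABET[c] for c in cols)


def pssm_from_sites(
    sites: list[str],
    pseudocount: float = 0.25,
    background: np.ndarray | None = None,
    name: str = "motif",
) -> PSSM:
    """Estimate a PSSM from aligned, equal-length literal sites.

    Column probabilities are (count + pseudocount) / (n + 4*pseudocount).
    """
    if not sites:
        raise ValueError("empty site list")
    w = len(sites[0])
    if any(len(s) != w for s in sites):
        raise ValueError("sites must all have the same length")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    counts = np.zeros((w, 4))
    for s in sites:
        oh = onehot(s)
        if oh.sum() != w:
            raise ValueError(f"site {s!r} contains non-ACGT characters")
        counts += oh
    matrix = (counts + pseudocount) / (len(sites) + 4 * pseudocount)
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    return PSSM(matrix, background=bg, pseudocount=pseudocount, name=name)


# ---------------------------------------------------------------------------
# Table 2 fixture: printed operator sites, anchored to a common 17-column core


def load_rdrm_sites() -> pd.DataFrame:
    """The packaged fixture of printed RDRM operator sites (18-20 nt)."""
    path = importlib.resources.files("rdrmap.data") / "rdrm_sites.tsv"
    with importlib.resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def align_sites(sites: list[str], width: int = 17, max_iter: int = 100) -> list[str]:
    """Anchor variable-length literal sites to a common-width core.

    Deterministic iterative profile alignment: start from the centre trim of
    each site, then repeatedly realign every site by exhaustive ungapped
    offset search against the current profile (smallest offset wins ties)
    until the alignment is stable.
    """
    if any(len(s) < width for s in sites):
        raise ValueError(f"all sites must be at least {width} nt")

    def centre(s: str) -> str:
        off = (len(s) - width) // 2
        return s[off : off + width]

    windows = [centre(s) for s in sites]
    for _ in range(max_iter):
        prof = np.log(
            pssm_from_sites(windows).matrix
        )  # profile log-probabilities
        new = []
        for s in sites:
            best_score, best_win = -np.inf, None
            for off in range(len(s) - width + 1):
                win = s[off : off + width]
                score = float((onehot(win) * prof).sum())
                if score > best_score + 1e-12:
                    best_score, best_win = score, win
            new.append(best_win)
        if new == windows:
            break
        windows = new
    return windows


def rdrm_fixture_pssm(pseudocount: float = 0.25) -> tuple[PSSM, list[str]]:
    """PSSM of the packaged operator-site fixture on the 17-column core."""
    sites = load_rdrm_sites()["site"].tolist()
    aligned = align_sites(sites, width=17)
    return pssm_from_sites(aligned, pseudocount=pseudocount, name="rdrm"), aligned


# ---------------------------------------------------------------------------
# Exact p-values on a discretised score lattice


class ScoreDistribution:
    """Exact log-odds tail probabilities under the 0-order background.

    Column scores are rounded onto an integer lattice (``n_bins`` bins over
    the total score range); the distribution of the total integer score of
    a random background word is built by column-wise convolution, and
    p(s) = Pr_bg(score >= s) read off the reversed cumulative sum.  Words
    are scored on the same rounded lattice, so lookups are exact for the
    discretised matrix.
    """

    def __init__(self, pssm: PSSM, n_bins: int = 10_000):
        self.pssm = pssm
        scores = pssm.log_odds()
        col_min = scores.min(axis=1)
        total_range = float(scores.max(axis=1).sum() - col_min.sum())
        if total_range <= 0:  # uniform matrix equal to background
            self.scale = 1.0
        else:
            self.scale = (n_bins - 1) / total_range
        # integer column scores, shifted so each column's minimum is 0
        self.int_scores = np.rint((scores - col_min[:, None]) * self.scale).astype(
            np.int64
        )
        self.offset = float(col_min.sum())  # real score of integer score 0
        dist = np.array([1.0])
        for col in self.int_scores:
            width = dist.size + col.max() + 1
            new = np.zeros(width)
            for b in range(4):
                new[col[b] : col[b] + dist.size] += pssm.background[b] * dist
            dist = new
        self.tail = np.cumsum(dist[::-1])[::-1]
        self.tail = np.minimum(self.tail, 1.0)

    def int_score(self, word: str) -> int | None:
        """Lattice score of a word, or None if it contains non-ACGT bases."""
        total = 0
        for i, b in enumerate(word):
            j = _IDX.get(b)
            if j is None:
                return None
            total += self.int_scores[i, j]
        return total

    def bits(self, int_score: int) -> float:
        """Approximate real score (bits) of a lattice score."""
        return self.offset + int_score / self.scale

    def pvalue(self, int_score: int) -> float:
        if int_score >= self.tail.size:
            return float(self.tail[-1])
        return float(self.tail[max(int_score, 0)])

    def pvalue_of_word(self, word: str) -> float:
        s = self.int_score(word)
        if s is None:
            raise ValueError("word contains non-ACGT bases")
        return self.pvalue(s)

    def threshold_score(self, p_threshold: float) -> int:
        """Smallest lattice score whose p-value is <= the threshold.

        Returns ``tail.size`` (unreachable) if no score is significant.
        """
        idx = np.searchsorted(-self.tail, -p_threshold, side="left")
        return int(idx)


def score_pvalues(pssm: PSSM, n_bins: int = 10_000) -> ScoreDistribution:
    """Build the exact score -> p-value lookup for a PSSM."""
    return ScoreDistribution(pssm, n_bins=n_bins)


# ---------------------------------------------------------------------------
# Promoter scanning


@dataclass
class MotifHit:
    """A significant PSSM match inside a promoter window.

    ``offset`` is the window offset (relative to the start codon, reading
    direction) of the leftmost base of the matched w-mer; ``strand`` is the
    strand of the match relative to the gene's reading direction.
    """

    gene_id: str
    offset: int
    strand: str
    score_bits: float
    p_value: float
    letters: str
    pssm_name: str = "motif"


def _scan_sequence(
    dist: ScoreDistribution, seq: str, min_int_score: int
) -> list[tuple[int, str, int, str]]:
    """(position, strand, int_score, letters) for all significant matches."""
    w = dist.pssm.width
    hits = []
    rc = revcomp(seq)
    n = len(seq)
    for strand, s in (("+", seq), ("-", rc)):
        oh = onehot(s)
        if n < w:
            continue
        # sliding integer scores; windows containing N (all-zero rows) dropped
        valid = oh.sum(axis=1)
        scores = np.zeros(n - w + 1, dtype=np.int64)
        ok = np.ones(n - w + 1, dtype=bool)
        for i in range(w):
            col = dist.int_scores[i]
            idx = oh[i : i + n - w + 1].argmax(axis=1)
            scores += col[idx]
            ok &= valid[i : i + n - w + 1] > 0
        for pos in np.nonzero(ok & (scores >= min_int_score))[0]:
            if strand == "+":
                left, letters = int(pos), s[pos : pos + w]
            else:
                left = n - w - int(pos)
                letters = s[pos : pos + w]
            hits.append((left, strand, int(scores[pos]), letters))
    return hits


def scan_promoters(
    pssm: PSSM,
    windows: list[PromoterWindow],
    p_threshold: float = 1e-4,
    background: np.ndarray | str | None = "auto",
    n_bins: int = 10_000,
) -> list[MotifHit]:
    """Scan both strands of promoter windows, reporting matches at p <= threshold.

    With ``background="auto"`` the 0-order background is estimated from the
    scanned windows themselves.  Matches overlapping N are never reported;
    multiple hits per window are allowed.
    """
    if background is None:
        scan_pssm = pssm
    else:
        bg = (
            background_from_sequences([w.sequence for w in windows])
            if isinstance(background, str)
            else np.asarray(background)
        )
        scan_pssm = PSSM(
            pssm.matrix, background=bg, pseudocount=pssm.pseudocount, name=pssm.name
        )
    dist = score_pvalues(scan_pssm, n_bins=n_bins)
    min_score = dist.threshold_score(p_threshold)
    out: list[MotifHit] = []
    for win in windows:
        for left, strand, int_score, letters in _scan_sequence(
            dist, win.sequence, min_score
        ):
            out.append(
                MotifHit(
                    gene_id=win.gene_id,
                    offset=win.first_offset + left,
                    strand=strand,
                    score_bits=dist.bits(int_score),
                    p_value=dist.pvalue(int_score),
                    letters=letters,
                    pssm_name=pssm.name,
                )
            )
    return out


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": h.gene_id,
                "offset": h.offset,
                "strand": h.strand,
                "score_bits": h.score_bits,
                "p_value": h.p_value,
                "letters": h.letters,
                "pssm": h.pssm_name,
            }
            for h in hits
        ],
        columns=[
            "gene_id", "offset", "strand", "score_bits", "p_value", "letters", "pssm",
        ],
    )


def write_hits_gff3(
    hits: list[MotifHit], genome, path: str, header: str = ""
) -> None:
    """Export promoter hits as GFF3 features at their genomic coordinates."""
    from .genome import promoter_window

    windows = {g.id: promoter_window(g, genome) for g in genome.cds()}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if header:
            fh.write(header)
        for i, h in enumerate(hits):
            win = windows[h.gene_id]
            w = len(h.letters)
            a = win.offset_to_genomic(h.offset)
            b = win.offset_to_genomic(h.offset + w - 1)
            start, end = min(a, b), max(a, b)
            # strand on the genome: gene strand flipped for '-' relative hits
            gstrand = win.strand if h.strand == "+" else (
                "-" if win.strand == "+" else "+"
            )
            fh.write(
                f"{win.replicon_id}\trdrmap\tTF_binding_site\t{start + 1}\t"
                f"{end + 1}\t{h.score_bits:.3f}\t{gstrand}\t.\t"
                f"ID=hit_{i};gene={h.gene_id};offset={h.offset};"
                f"pvalue={h.p_value:.3g};motif={h.pssm_name}\n"
            )


# ---------------------------------------------------------------------------
# IUPAC consensus


def iupac_consensus(pssm: PSSM, freq_threshold: float = 0.25) -> str:
    """Minimal IUPAC code per column covering all bases at >= threshold.

    Columns where no base reaches the threshold fall back to the single
    most probable base.
    """
    out = []
    for col in pssm.matrix:
        bases = frozenset(
            b for b, p in zip(ALPHABET, col) if p >= freq_threshold
        )
        if not bases:
            bases = frozenset(ALPHABET[int(np.argmax(col))])
        out.append(IUPAC_CODES[bases])
    return "".join(out)


def consensus_match_positions(query: str, reference: str) -> int:
    """Best ungapped-alignment count of IUPAC-compatible positions.

    Two degenerate codes match when their base sets intersect — the
    standard comparison for consensus strings produced under different
    degenerate-coding conventions.  The shorter string is slid along the
    longer one and the best offset is reported.
    """
    short, long_ = sorted((query, reference), key=len)
    best = 0
    for off in range(len(long_) - len(short) + 1):
        m = sum(
            bool(IUPAC_SETS[a] & IUPAC_SETS[b])
            for a, b in zip(short, long_[off : off + len(short)])
        )
        best = max(best, m)
    return best


# ---------------------------------------------------------------------------
# ZOOPS EM discovery


@dataclass
class EMResult:
    pssm: PSSM
    log_likelihood: float
    bic: float
    gamma: float
    ll_trace: list[float]
    # penalized objective (LL + Dirichlet log-prior from the pseudocounts);
    # this, not the raw LL, is what MAP-EM makes non-decreasing
    objective_trace: list[float] = field(default_factory=list)


def _em_one_start(
    windows_fwd: list[np.ndarray],
    windows_rev: list[np.ndarray],
    init_matrix: np.ndarray,
    background: np.ndarray,
    palindrome: bool,
    gamma0: float = 0.5,
    pseudocount: float = 0.25,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> EMResult:
    """Run ZOOPS EM from one initial matrix; LL is monotone by construction."""
    matrix = init_matrix.copy()
    gamma = gamma0
    log_bg = np.log(background)
    w = matrix.shape[0]
    ll_trace: list[float] = []
    obj_trace: list[float] = []
    for _ in range(max_iter):
        log_mat = np.log(matrix) - log_bg  # log likelihood-ratio per column/base
        counts = np.zeros((w, 4))
        gamma_num = 0.0
        ll = 0.0
        for fwd, rev_ in zip(windows_fwd, windows_rev):
            m = fwd.shape[0]
            if m == 0:
                continue
            # log LR of a site at each position/strand
            lr_f = np.einsum("pwb,wb->p", fwd, log_mat)
            lr_r = np.einsum("pwb,wb->p", rev_, log_mat)
            lr = np.exp(np.concatenate([lr_f, lr_r]))
            site_prior = gamma / (2 * m)
            denom = (1 - gamma) + site_prior * lr.sum()
            ll += np.log(denom)
            post = site_prior * lr / denom
            gamma_num += post.sum()
            pf, pr = post[:m], post[m:]
            counts += np.einsum("p,pwb->wb", pf, fwd)
            counts += np.einsum("p,pwb->wb", pr, rev_)
        ll_trace.append(ll)
        obj_trace.append(ll + pseudocount * float(np.log(matrix).sum()))
        if len(obj_trace) > 1 and obj_trace[-1] - obj_trace[-2] < tol:
            break
        if palindrome:
            counts = 0.5 * (counts + counts[::-1, ::-1])
        counts += pseudocount
        matrix = counts / counts.sum(axis=1, keepdims=True)
        gamma = min(max(gamma_num / len(windows_fwd), 1e-4), 1 - 1e-4)
    n_seq = len(windows_fwd)
    k = 3 * w + 1
    bic = -2 * ll_trace[-1] + k * np.log(max(n_seq, 2))
    return EMResult(
        pssm=PSSM(matrix, background=background, name=f"em_w{w}"),
        log_likelihood=ll_trace[-1],
        bic=bic,
        gamma=gamma,
        ll_trace=ll_trace,
        objective_trace=obj_trace,
    )


def discover_motifs(
    sequences: list[str],
    width_range: tuple[int, int] = (15, 20),
    mode: str = "palindrome",
    n_starts: int = 10,
    seed: int = 0,
    max_models: int = 4,
    pseudocount: float = 0.25,
    max_iter: int = 500,
    init_weight: float = 0.8,
    gamma0: float = 0.6,
) -> list[EMResult]:
    """De novo ZOOPS EM motif discovery over both strands.

    For each width in ``width_range`` (inclusive), ``n_starts`` EM runs are
    seeded from random w-mers of the input and the best run by final
    log-likelihood kept (smallest start index wins exact ties).  Models
    across widths are ranked by BIC and the top ``max_models`` returned.
    ``mode`` is "palindrome" (matrix constrained reverse-complement
    symmetric each M-step) or "any".
    """
    if mode == "both":
        half = [
            discover_motifs(
                sequences, width_range, m, n_starts, seed, max_models,
                pseudocount, max_iter, init_weight, gamma0,
            )
            for m in ("palindrome", "any")
        ]
        pooled = sorted(half[0] + half[1], key=lambda r: r.bic)
        return pooled[:max_models]
    if mode not in ("any", "palindrome"):
        raise ValueError("mode must be 'any', 'palindrome' or 'both'")
    if len(sequences) < 5:
        raise ValueError("need at least 5 sequences")
    usable = [s.upper() for s in sequences]
    background = background_from_sequences(usable)
    rng = np.random.default_rng(seed)
    lo, hi = width_range
    if any(len(s) <= hi for s in usable):
        raise ValueError("all sequences must be longer than the maximum width")
    results: list[EMResult] = []
    palindrome = mode == "palindrome"
    for w in range(lo, hi + 1):
        wins_f, wins_r = [], []
        for s in usable:
            oh = onehot(s)
            n = len(s)
            sw = np.lib.stride_tricks.sliding_window_view(oh, (w, 4)).reshape(
                n - w + 1, w, 4
            )
            valid = sw.sum(axis=(1, 2)) == w  # drop windows overlapping N
            sw = sw[valid]
            wins_f.append(sw)
            wins_r.append(sw[:, ::-1, ::-1])
        if all(x.shape[0] == 0 for x in wins_f):
            raise ValueError("no scannable windows (all-N sequences?)")

        def run(init, iters):
            return _em_one_start(
                wins_f, wins_r, init, background, palindrome=palindrome,
                gamma0=gamma0, pseudocount=pseudocount, max_iter=iters,
            )

        # start selection: short EM trials on many candidate seed words,
        # full EM only on the most promising n_starts of them
        trials: list[tuple[float, np.ndarray]] = []
        for _trial in range(30 * n_starts):
            si = int(rng.integers(len(usable)))
            seq = usable[si]
            pos = int(rng.integers(max(len(seq) - w, 1)))
            seed_word = onehot(seq[pos : pos + w])
            init = init_weight * seed_word + (1 - init_weight) * np.tile(
                background, (w, 1)
            )
            if palindrome:  # project the start into the constraint set so
                # the constrained M-step keeps the likelihood monotone
                init = 0.5 * (init + init[::-1, ::-1])
            init /= init.sum(axis=1, keepdims=True)
            short = run(init, 2)
            trials.append((short.log_likelihood, init))
        trials.sort(key=lambda t: -t[0])
        best: EMResult | None = None
        for _ll, init in trials[:n_starts]:
            res = run(init, max_iter)
            if best is None or res.log_likelihood > best.log_likelihood:
                best = res
        # phase polishing: try small column shifts of the converged matrix
        for shift in (-2, -1, 1, 2):
            shifted = np.tile(background, (w, 1))
            if shift > 0:
                shifted[: w - shift] = best.pssm.matrix[shift:]
            else:
                shifted[-shift:] = best.pssm.matrix[: w + shift]
            if palindrome:
                shifted = 0.5 * (shifted + shifted[::-1, ::-1])
            res = run(shifted / shifted.sum(axis=1, keepdims=True), max_iter)
            if res.log_likelihood > best.log_likelihood + 1e-9:
                best = res
        results.append(best)
    results.sort(key=lambda r: r.bic)
    return results[:max_models]


def pssm_distance(a: PSSM, b: PSSM, max_shift: int = 3) -> float:
    """Mean per-column total-variation distance, minimised over strand and
    small phase shifts (shifted-out columns compared against background).

    An EM motif model is identified only up to phase and strand, so the
    comparison aligns the two matrices before averaging column TV.
    """
    def tv(m1: np.ndarray, m2: np.ndarray) -> float:
        return float(0.5 * np.abs(m1 - m2).sum(axis=1).mean())

    def shifted(mat: np.ndarray, shift: int, bg: np.ndarray) -> np.ndarray:
        w = mat.shape[0]
        out = np.tile(bg, (w, 1))
        if shift >= 0:
            out[: w - shift] = mat[shift:]
        else:
            out[-shift:] = mat[: w + shift]
        return out

    if a.width != b.width:
        raise ValueError("matrices must have equal width")
    best = np.inf
    for mat in (a.matrix, a.matrix[::-1, ::-1]):
        for shift in range(-max_shift, max_shift + 1):
            best = min(best, tv(shifted(mat, shift, a.background), b.matrix))
    return best


# ---------------------------------------------------------------------------
# MEME minimal-format I/O


def write_meme(pssms: list[PSSM], path: str) -> None:
    """Write PSSMs in MEME minimal text format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pssms[0].background if pssms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {p:.6f}" for b, p in zip(ALPHABET, bg)) + "\n\n"
        )
        for p in pssms:
            fh.write(f"MOTIF {p.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {p.width} "
                f"nsites= 10000 E= 0\n"
            )
            for row in p.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_meme(path: str) -> list[PSSM]:
    """Read PSSMs from MEME minimal text format."""
    pssms: list[PSSM] = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            background = np.array([float(parts[j]) for j in (1, 3, 5, 7)])
            background /= background.sum()
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while "letter-probability matrix" not in lines[i]:
                i += 1
            w = int(lines[i].split("w=")[1].split()[0])
            rows = []
            for j in range(w):
                rows.append([float(x) for x in lines[i + 1 + j].split()])
            mat = np.array(rows)
            mat /= mat.sum(axis=1, keepdims=True)
            pssms.append(PSSM(mat, background=background.copy(), name=name))
            i += w + 1
            continue
        i += 1
    return pssms
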