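#!/usr/bin/env python
"""Ka/Ks estimation, sliding-window selection profile, and Ks dating.

Simulates CDS pairs at controlled divergence, estimates Ka/Ks with the
pathway-counting method, profiles a pair with a planted positively
selected core using 150 bp / 9 bp sliding windows, and dates the reference
Ks values 0.15 and 0.25 under the 6.5e-9 synonymous clock (11.54 and
19.23 MY).
"""

import argparse
import json
from pathlib import Path

from iqdfam.kaks import (
    CodonAlignment,
    classify_selection,
    date_divergence,
    kaks_estimate,
    sliding_window_kaks,
)
from iqdfam.simulate import gen_diverged_cds_pair

OUT = Path(__file__).resolve().parent.parent / "results"


def _pair_alignment(a: str, b: str) -> CodonAlignment:
    return CodonAlignment([(a[i:i + 3], b[i:i + 3]) for i in range(0, len(a), 3)])


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-pairs", type=int, default=20)
    args = ap.parse_args()

    lines = ["pair\tka\tks\tratio\tselection\trealized_ks\tt_mya"]
    for i in range(args.n_pairs):
        a, b, truth = gen_diverged_cds_pair(args.seed + i, n_codons=500,
                                            target_ks=0.2, omega=0.2)
        res = kaks_estimate(_pair_alignment(a, b))
        date = date_divergence(res.ks)
        lines.append(
            f"pair{i}\t{res.ka:.4f}\t{res.ks:.4f}\t"
            f"{'NA' if res.ratio is None else f'{res.ratio:.3f}'}\t"
            f"{classify_selection(res.ratio)}\t{truth.realized_ks:.4f}\t{date.t_mya:.2f}"
        )
    OUT.mkdir(exist_ok=True)
    (OUT / "kaks_pairs.tsv").write_text("\n".join(lines) + "\n")

    # sliding-window profile over a pair with a positively selected core
    fa, fb, _ = gen_diverged_cds_pair(args.seed + 100, n_codons=100, target_ks=0.25, omega=0.05)
    ca, cb, _ = gen_diverged_cds_pair(args.seed + 101, n_codons=50, target_ks=0.25, omega=3.0)
    track = sliding_window_kaks(_pair_alignment(fa + ca + fa, fb + cb + fb))
    wlines = ["start_bp\tend_bp\tka\tks\tratio"]
    for start, end, res in track.windows:
        ratio = "NA" if res.ratio is None else f"{res.ratio:.3f}"
        ks = "NA" if res.ks is None else f"{res.ks:.4f}"
        ka = "NA" if res.ka is None else f"{res.ka:.4f}"
        wlines.append(f"{start}\t{end}\t{ka}\t{ks}\t{ratio}")
    (OUT / "kaks_windows.tsv").write_text("\n".join(wlines) + "\n")

    dating = {
        str(ks): {"t_mya": date_divergence(ks).t_mya,
                  "t_mya_nearest": date_divergence(ks).t_mya_nearest}
        for ks in (0.13, 0.15, 0.25)
    }
    (OUT / "dating.json").write_text(json.dumps(dating, indent=1))
    print(json.dumps(dating, indent=1))
    best = max((w for w in track.windows if w[2].ratio is not None),
               key=lambda w: w[2].ratio)
    print(f"max-ratio window {best[0]}-{best[1]} bp (planted core 300-450 bp), "
          f"ratio {best[2].ratio:.2f}")


if __name__ == "__main__":
    main()
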