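"""Width calibration for the default configuration.

The publication reports total size (0.45 M / 17.00 G for the plain-decoder
model, 0.57 M / 18.06 G for the full model at 512x512) but not the layer
widths.  This script searches stem width, decoder widths and guide-transform
widths for the combination whose parameter count and analytic FLOPs best
match all four figures simultaneously, using the package's own builders, and
prints the best candidates.  The shipped defaults
(stem 5, decoder (24, 96, 132, 28), guide (96, 58)) are its output.

Run:  python scripts/calibrate_widths.py  [--fast]
"""

import argparse
import itertools

from dcsanet import ModelConfig, build_model, model_summary

TARGETS = {"full_p": 0.57, "plain_p": 0.45, "full_f": 18.06, "plain_f": 17.00}


def measure(stem, decoder, guide):
    common = dict(
        stem_channels=stem,
        stage_widths=(2 * stem, 4 * stem, 16 * stem),
        decoder_widths=decoder,
        guide_widths=guide,
    )
    plain = model_summary(
        build_model(ModelConfig(decoder_variant="plain", **common)), input_size=512
    )
    full = model_summary(
        build_model(ModelConfig(decoder_variant="feat3_guided_residual", **common)),
        input_size=512,
    )
    return {
        "full_p": full.params_millions,
        "plain_p": plain.params_millions,
        "full_f": full.flops_billions,
        "plain_f": plain.flops_billions,
    }


def relative_error(measured):
    return max(abs(measured[k] - v) / v for k, v in TARGETS.items())


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--fast", action="store_true",
                        help="search a small neighbourhood of the shipped defaults")
    args = parser.parse_args()

    if args.fast:
        stems = [5]
        d1s, d2s, d3s, d4s = [24], [92, 96], [128, 132], [28]
        g1s, g2s = [96], [56, 58, 60]
    else:
        stems = [4, 5, 6]
        d1s = range(16, 49, 8)
        d2s = range(80, 113, 8)
        d3s = range(112, 145, 8)
        d4s = range(24, 41, 4)
        g1s = range(72, 105, 8)
        g2s = range(50, 75, 4)

    best = []
    for stem, d1, d2, d3, d4 in itertools.product(stems, d1s, d2s, d3s, d4s):
        # prune on the plain model first: it does not depend on the guide
        plain = model_summary(
            build_model(ModelConfig(
                stem_channels=stem, stage_widths=(2 * stem, 4 * stem, 16 * stem),
                decoder_widths=(d1, d2, d3, d4), decoder_variant="plain",
            )),
            input_size=512,
        )
        if abs(plain.params_millions - TARGETS["plain_p"]) / TARGETS["plain_p"] > 0.015:
            continue
        if abs(plain.flops_billions - TARGETS["plain_f"]) / TARGETS["plain_f"] > 0.015:
            continue
        for g1, g2 in itertools.product(g1s, g2s):
            m = measure(stem, (d1, d2, d3, d4), (g1, g2))
            err = relative_error(m)
            if err < 0.015:
                best.append((err, stem, (d1, d2, d3, d4), (g1, g2), m))

    best.sort(key=lambda t: t[0])
    if not best:
        print("no candidate within 1.5% of all four targets; widen the grid")
        return
    for err, stem, decoder, guide, m in best[:10]:
        print(
            f"err={err:.4f}  stem={stem} decoder={decoder} guide={guide}  "
            f"plain=({m['plain_p']:.4f} M, {m['plain_f']:.2f} G)  "
            f"full=({m['full_p']:.4f} M, {m['full_f']:.2f} G)"
        )


if __name__ == "__main__":
    main()
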