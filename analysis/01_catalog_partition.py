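"""Catalog and pair-partition facts of the 25-region network layout.

Writes the full pair classification table and prints the partition
counts: the 14 core regions give 27 within- and 64 between-network
pairs; all 25 regions give 300 pairs (68 within / 232 between) under
the I(8)/II(6)/III(5)/IV(6) partition.
"""

from pathlib import Path

from syntaxconn import classify_pairs, default_catalog, network_sizes

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    catalog = default_catalog()
    print(f"regions: {len(catalog)} "
          f"(core {len(catalog.core())}, additional {len(catalog.additional_regions())})")
    print(f"network sizes: {network_sizes(catalog)}")

    pairs = classify_pairs(catalog)
    core = classify_pairs(catalog.core())
    print(f"all 25 regions: {len(pairs)} pairs "
          f"({pairs.n_within} within, {pairs.n_between} between)")
    print(f"core 14 regions: {len(core)} pairs "
          f"({core.n_within} within, {core.n_between} between)")

    OUT.mkdir(exist_ok=True)
    pairs.to_frame().to_csv(OUT / "pair_classification.tsv", sep="\t", index=False)
    print(f"wrote {OUT / 'pair_classification.tsv'}")


if __name__ == "__main__":
    main()
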