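"""Enumerate the barcode space and the six-channel acquisition scheme.

Three dyes (DiO, DiI, DiD) at three levels (0, 1, 10 uM) give n**m - 1 = 26
usable barcodes; six confocal channels pair each laser line with every
emission window above it.
"""

from nanobarcode import barcode_table, channel_table, enumerate_barcodes, valid_channel_pairs

codes = enumerate_barcodes()
print(f"{len(codes)} barcodes from 3 levels x 3 dyes (all-zero excluded)\n")
print(barcode_table(codes).to_string(index=False))

print("\nAcquisition channels (laser / emission window, nm):")
print(channel_table().to_string(index=False))

pairs = valid_channel_pairs(
    [488.0, 552.0, 638.0],
    [(498.0, 538.0), (563.0, 620.0), (648.0, 750.0)],
)
print(f"\n{len(pairs)} valid laser/window pairs -> every emission window sits above its laser line")
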