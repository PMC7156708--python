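# Add-back list: tokens removed from the whitelist because they are census
# or SSA names, re-inserted because their common-word sense dominates in
# clinical narrative and losing them costs too much precision.
white
green
brown
gray
black
stone
snow
rice
banks
rose
young
king
marshall
woods
fisher
bishop
summers
winters
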