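# Curated starter exclusion list: name tokens that are overwhelmingly more
# often common words than names in clinical text, removed from both
# blacklists to protect precision. The original production list was larger
# and tuned on a private development corpus; this set is representative.
new
walks
knee
home
child
may
june
april
august
summer
autumn
dawn
long
west
cook
price
wells
ward
ford
bell
hall
ray
grace
hope
joy
faith
penny
iris
olive
daisy
lily
violet
hazel
pearl
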