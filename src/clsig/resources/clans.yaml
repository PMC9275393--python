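# Standard IGHV phylogenetic clan membership, by IMGT family.
# Clan I: IGHV1/5/7; Clan II: IGHV2/4/6; Clan III: IGHV3.
# Editable: supply your own table to ClanTable.from_yaml for updated references.
clans:
  IGHV1: I
  IGHV5: I
  IGHV7: I
  IGHV2: II
  IGHV4: II
  IGHV6: II
  IGHV3: III
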