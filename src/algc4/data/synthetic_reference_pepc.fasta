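>PEPC_REF_SYN|synthetic reference|other|PEPC
QFGPQSPSPENTREQQFMHETQYKLDCNQVYSGFYVNNNRCDKQLFAPTLQMNICPLWMKRWPLCDLCWT
TWVRPCLSQNLLYAFWKCNREIKLIPESTHSVNTFGYCVQSSLITAQNSYVDKNRLQSEMLEYTFWPHNW
RIRMWWHQVDNKFWKRMRMQYAGYMENQHSGHGTVIDNIRSRPASQQEKAQIVQFRLTVQQKTGREHWDT
MWDCNCCFERDAIMANGHMCEGAPYEPIWAGLCMRRELLPQGWYEWNTPAILCPMRHECDVYGSSWQTRI
CHERQGGWRCRWPLWSADEELAAHAIQWKHGHFMVMFDKREHIVWVHNFMGVKIYDFKNAHNMDLAQTTG
CAMDVMKGESSMIPCSTHKLASKLPRNPWFIGAQIKQDLCCAWLFLDWVNAQFGPDHNQMGHSEKWAQYD
APMYDRLSVWHAADQSWWDWNCANRIAKILGQIERHMDQHFNTMVYYYDFAMDVFFDDNFLAHFYPRQVH
TWQQNGLIQEAMGDFTLYCQWQRCMGHIGVENHCRMDDFTVSNFWWVGLDFWWAYCIPQEEEECDKNRFC
MFNMRVMTHNTFACQMDTTCKEEQPLAQRREVTNRVNVNAMNHPTHDQGLNTLMQWRLLGVQLIGSMWAT
YGIYPIPIRVPACVYNIPRAINDRQRQERKRNQRGIEALGKHHCMNASLLYRTHRFCGHSHIDCHFENPG
LQFRARNTYDNSRTLQKAAHRDSFALISPIKRTIRTYEGREIQDRAAYLKAAMHKPCILLWIEITNQKKC
GGSSGACLIPVFWEVPIDIHDYRYDNAFLSLRQGDIIKYANQNFYRGTPCSKYDYCACFFNNCWFGLHGY
GYGIVLYHPSAFPPPSKMCWTKVDDYHHRKSMISEFDFTKEHEYAGERVEAGTCMSNEKPEQEYMSIMGP
EGRHAAQNTG
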