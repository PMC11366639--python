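substrate	code	full_sequence	provenance
Ser	SCKITRVDWA	VDAQLRDKQNESIFYSLIFGGLATCVDSSRQHDIRLKFWGWIHIWWGIIDWNEKDKGTCKYMSSGRMGILDWKPVPVYSDSSQDPVWYSAYQPDCWGWMWKQAVACHHDMIISAPPGAAQ	synthetic reference library
Gly	VLGSNVRLKK	VDAQLRDKQNEVIFQSLIFGGLATLVDSSRQHDIRLGQWGWIHIWWGQSDWNEKDKGNCKQMQSGVMGILDWKPRPVYSDSSQLPVWYSNYQTDCKGWMWKQAVKYHHDMIISAPPGAAQ	synthetic reference library
Ala	HKMMMDKEMQ	VDAQLLDKQNEHIFQSLIFGGLATKVDSSRQHDIRLMQWGWIHIWWGIMDWNEKDKGMCKQMLSGDMGILDWKPKPVYSRSSQEPVWYSNYQPDCMGWMWKQAVQCHHDMDICAPPCNAM	synthetic reference library
Thr	HGFRPCSWWF	VDAGLRDKQNEHIFQSLIFGGLATGVDSSRQHDIRKFQWGWIHIWWGIRDWNEKDKLPCKQMLSGCMGILDWKPSPVYSDSSQWPVWYHNYQPDCWGWMWKQAVFCHHDMIIVAPPGAAQ	synthetic reference library
Orn	ASVQCTWTDC	VDAQLRDKQNEAIFQSLIFLGLATSVDSSRQHMIRLVQWGEIHIWWGIQDWNEKDKGCCKQMLSGTMGILDWKPWPVYSDSSQTPVWQQNYQPDCDGWMWKQAVCCHHDYIISAPPGAAQ	synthetic reference library
Lys	MIYNMEPQAF	VDAQLRDKQNEMIFQSLIFGGLATIVDSSRQHDIRNYQWGWIHGWGGINDWNEKDKGMCKQMLSGEMGILDWTPPPVYSDSSQQPVWYSNYQPDCAGWMWKQAVFCHHDMIISEPPGAAQ	synthetic reference library
Arg	EILTVVCINL	VDAQLRDKQNMEIFQSLIFGGLATIVDSSRQHDIRLLTWGWIHIWWGITDWNGKDKGVCKQMLSGVMGILDWKPCPVYSDSSQIPVWQSNYQPDCNGWMWKQAVLCHHDMIISAPPGAAE	synthetic reference library
Glu	ARSVQVEMEI	VDAQLRDKQNEASFQSLIFGGLATRVDSSRQHDIRLSQWGCIHIWWGIVDWNEHDKGQYKLMLSGVMGILDWKPEPVYSDSSQMPVWYSNYQPDCEGWMWKQAVICHHDMIISAPPGAAQ	synthetic reference library
Tyr	QCTGIAPFSG	VDAQLRDKQNEQIFQSLIFGGLATCVDSSRQHDIRLTQWGWIHIWWGIGDWNEKDKGICKQMLSGAMGILDWHQPPVYSDSSQFPVWYSNYQPDCSGWMWKQAVGCHHDMIISAPPGAAQ	synthetic reference library
Dab	YYRWLEKFPA	VDAQLRDKQNEYIFQSLIFGGLANYVDSSRQHDIRLRQWGWIHIWWGIWFWNEKDKGLCKQMLSGEMGILDWKPKSVYSDSSQFPVWYSNYQPDCPGWMWPQAVACHHDMIISRPPGSAQ	synthetic reference library
Asp	HTATWWYEPS	VDAQLRDKQNEHIFQSLIFGGLATTVDSIVQHDIRLAQWGWIHIWWGITDWNEKLKGWCKQMLSGWMGYLDWKPYPVYSDESQEPVWYSNYQPDCPGWMWKQAVSCHHDMIISAPPGAAQ	synthetic reference library
Hse	DNEPAAPVCC	VDAQLRDKQNSDIFQSIIFGGLATNVDSSRQHDIRLEQWGWIHIWWGIPLYNEKDKGACKQMLSGAMGILDWKPPPVYSDRSQVPVWYSNYQPDCCGWMWKQAVCCHHDMIISAPPGAAQ	synthetic reference library
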