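>GAG capsid-like (virus-like particle) protein core (synthetic, 139 aa)
NHAAKQHNWHKRLERRREMMQRMYIQYHRPTPGGFKAGQWQHQDYKIWNTTQPLSEIISA
DFPLLMMNQHFLMILVRMRDATADFGLTAQYISHLYAHWYYSTFQQHNLGCEVFRPVTEV
ETLKMFSSQIRKCMKVMMD
>AP aspartic protease (synthetic, 104 aa)
GSSWDSWCVWGCKGSAAAHWNTFEIYVLALRDWTKKITNHSFVQESCNWLHHWGSACHYI
GWMVYKKANHMIHMPAINIMIVIHPHPPPPPCDKCCKLCMDSQL
>INT integrase core (synthetic, 205 aa)
AYEDGSICWVFRKICFDEGHFMEYDWTQDKHIRSGDPVALGAFKASNVDVNFSHADSCQR
KVVLPCYFYIQHQCPNHGREYGDRFAHGLNRETLTNTTLVVYPHYLKHQTGYFHNSKTYY
GWMQHTEDNYHGFQAQTFWNINSNTVHTVFGISPQRAWKERHYHMYNQRCITQGKHRVGR
HQLTEEKVEYREWVVHKWEQRGWVT
>RT reverse transcriptase core (synthetic, 252 aa)
KNVWMQAVFGHVCMDGIIWQGLFKLPPRAADWDIRYELEDALVDRNTETHENFDGYKTYI
DKLIPFMYKPMYTIVLIYGIYYRHSYDDAIMIEYAGYCDIGDTVSICIGEWDQQQNTWRS
TGGTWVLKESQVEYEAKDSECLVGYPVSPFMGVSTKTPEMMPPQDPKRHSNNSYDQNTTK
ENNYKRKPSNYHANIHQSEGHQWNRYLDETIMMMSHTMWLPYEIDSAEHHLRYWDQLDPM
VGVQCHMESEPQ
>RH RNase H (synthetic, 130 aa)
HMKELKRRSARGAEQVYIRNICDYMLLNMLSFVLMKGVCPECVRHRQMAIHCEDYRYYHW
RQTWGHMVYFICEAERNTHSTQLFMDQPPPVHDWNMWSVYSIKDRRKECHVIFMVPTYKW
DGMNNEYDYC
>host_UBP host ubiquitin-specific-protease-like domain (synthetic, 181 aa)
SDLSHLRNICGPHTSNMIIYMAGMVIMQFQDQFATQDQSAKWRDSNPWTQFHEPWTQTKG
FCTCRSWRSAFKKNYKIDPDERAGQKNFAFRRHAAWFQIVFNNNTDNMPHTMAFPERKGP
VNACHVTTNHFEKMVQHDLRLHFWVYDWQEECPWSGWNKDTLCQTYNLQQKTHIMRRDKV
C
>host_KELP host KELP/PC4-like transcriptional coactivator domain (synthetic, 84 aa)
CCYFPHAQQGQGDEQGDCMVDHVTIDMWNKMIYGIFSSSKHNDDIDKHILLFCWLKCSQE
RWQYEETRKDAIPHERQGWNIIYL
>host_NTF2 host nuclear transport factor 2-like domain (synthetic, 118 aa)
GFFKGMNVGTSVVNHVAHYWNMCSQDHGMLVSMVSCDYPHQMQLPQHAHWHHIWLRLADC
HYCPNYMNNFLQGYQVSNPMYIWVDNHGWSTWFCWYNVDAIMPKCVVWPSVVYMYSEV
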