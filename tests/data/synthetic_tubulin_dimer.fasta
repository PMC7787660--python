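>synthetic_tubulin_alpha_like | SYNTHETIC stand-in chain, 24 sulfur residues (M+C)
DSCKKVDRFDCYSSRTNEVLNIFWTQKTNKLGDNVDVTGQESRIDYMWRTSFILLANESR
WMIYCHWIDLTFLMRLHGPRMKETQRDHSTKTVIWHGRQETFTATTTQLRGTPLNPAEGE
KRQLVPDSPQPNDPTHPAIKYFGKYVAGTDVHWHKQEPNTYQKKKTHFIADDSSRLREWN
WELRCLEIGHRQPIMDIEIYIWLRLGSYGTMRTLMGDDLWELRFRHTPNFLVASLRQKHC
EPDQQDSKTAFLFHQERCFPTFHWCPLIQPHAEYKCLTDDGLRLKWMPNLTGYHNNVKHA
ITAWNEHNHDQREHGQMSWSHDQWYGGAMNCIHTLTYHFYQHQNWGYWFENAHKYYEWDS
MWGWEMLHASIQKIVDSSIGAWYGAEDTWESFIPRCAFHHYSHYLNKEWAFGHEARCEHN
WRSPKFVCARDSTEKEPWDKYHELNQHYNHY
>synthetic_tubulin_beta_like | SYNTHETIC stand-in chain, 25 sulfur residues (M+C)
WKEQYVGLNGGGYSVTYDVDLPIEFTHHWEWWPEEHPELCNARAFFTAKPCRTKCHCNSV
TVNALFWMGGQPYKHAAIWNWDDVDAKWRDVVTWGMHTPTQQQTSETNHNYVVLTIRQCG
DEKLEKPGIIMISHKIFRGHTMRWVLSHLNYVLQFTNNSQDHFSAFPRNVWEYMQDQSPM
NWSECYFTKPLTYTWYDGRCADNQFFEPAPLLRNSSWTNLGPEWVETERDLQSKWSFRSI
SWTSQGTINHHEYEDWNKSIMSFNCWICQLEIQYARMYKEGVVQEELPARNADLSTKHYL
HKAHNWSTNDKYAVRHTVADQYAQEQQDRWVAGGLEVSTMAWHQWAAAEATPYTYGHVGD
RTYWESVRTCLALFEERNNSNQDVLETSAFAGDRNYSQNADQACFVLRKFIDMFIYPLNC
GQVMLEGYNHKPMRGQKWMELNRKW
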